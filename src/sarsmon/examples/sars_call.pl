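% Call-the-doctor example for a suspected severe respiratory distress case.
% Evidence strengths: white blood cell count elevated with probability 0.5,
% tachypnea (rapid breathing) 0.6, fever 0.9, and a confirmed drop in blood
% oxygen saturation (probability 1.0).
0.5::wbc_high.
0.6::tachypnea.
0.9::fever.
1.0::low_spo2.

% Distress is suspected when fever co-occurs with desaturation.
sars_suspected :- fever, low_spo2.

% The doctor is called when suspicion is corroborated by either lab or
% respiratory evidence (noisy-or across the two routes).
call_doctor :- sars_suspected, wbc_high.
call_doctor :- sars_suspected, tachypnea.
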