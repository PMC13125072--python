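# Threshold profile transcribing the printed sensor-agent rule table
# verbatim, including its idiosyncrasies: blood oxygen saturation is flagged
# High at >= 90 (no low rule), and the ECG cutoffs use the 0.6-1.2 scale.
name: paper_faithful
vitals:
  room_temp_c:
    vital: room_temp_c
    units: degC
    high: 35.0
    low: 15.0
    high_rule: R2
    low_rule: R3
    normal_rule: null
    high_predicate: Room_Temperature_Status
    low_predicate: Room_Temperature_Status
    tell_high: false
    tell_low: false
    low_message_level: Low
  spo2:
    vital: spo2
    units: percent
    high: 90.0
    low: null
    high_rule: R4
    low_rule: null
    normal_rule: null
    high_predicate: Current_BOS_Level
    low_predicate: null
    tell_high: true
    tell_low: false
    low_message_level: Low
  body_temp_c:
    vital: body_temp_c
    units: degC
    high: 39.0
    low: 37.0
    high_rule: R7
    low_rule: R9
    normal_rule: R11
    high_predicate: Has_Fever
    low_predicate: Has_Hypothermia
    tell_high: true
    tell_low: true
    low_message_level: High   # told as a high degree of hypothermia
  heart_rate:
    vital: heart_rate
    units: bpm
    high: 100.0
    low: 60.0
    high_rule: R12
    low_rule: R14
    normal_rule: R15
    high_predicate: High_Heart_Rate
    low_predicate: Low_Heart_Rate
    tell_high: true
    tell_low: false
    low_message_level: Low
  blood_sugar:
    vital: blood_sugar
    units: mg/dL
    high: 150.0
    low: 70.0
    high_rule: R16
    low_rule: R18
    normal_rule: R19
    high_predicate: High_Blood_Sugar
    low_predicate: Low_Blood_Sugar
    tell_high: true
    tell_low: false
    low_message_level: Low
  ecg_index:
    vital: ecg_index
    units: index (0.6-1.2 scale)
    high: 1.2
    low: 0.6
    high_rule: R20
    low_rule: R22
    normal_rule: R23
    high_predicate: Abnormal_ECG
    low_predicate: Low_Abnormal_ECG
    tell_high: true
    tell_low: false
    low_message_level: Low
blood_pressure:
  high_systolic: 145.0
  high_diastolic: 100.0
  low_systolic: 100.0
  low_diastolic: 60.0
  high_rule: R24
  low_rule: R26
  normal_rule: R27
  high_predicate: High_Blood_Pressure
  low_predicate: Low_Blood_Pressure
  tell_high: true
  tell_low: false
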