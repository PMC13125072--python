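"""Exact inference over small probabilistic-logic programs.

A program consists of independent probabilistic facts (``0.9::fever.``) and
definite clauses over them (``call_doctor :- fever, low_spo2.``). Under
possible-world semantics every fact is independently true or false per
world; the marginal probability of an atom is the total weight of the worlds
in which it is derivable by forward chaining. Multiple clauses for one head
combine as logical OR across worlds (noisy-or for independent single-fact
bodies). Negation and probabilistic clause heads are not supported; the
dependency graph must be acyclic.

Two inference routes are provided: :func:`enumerate_worlds` materializes all
``2^|facts|`` worlds (the brute-force oracle), while :meth:`ProbProgram.query`
uses Shannon expansion over the facts with early termination — the same
semantics computed by a different algorithm, usually visiting far fewer
branches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["ProbFact", "Clause", "ProbProgram", "parse_program", "query",
           "enumerate_worlds", "load_example", "ProgramError"]

DEFAULT_WORLD_CAP = 20


class ProgramError(ValueError):
    """Raised for malformed programs: syntax, duplicates, cycles."""


@dataclass(frozen=True)
class ProbFact:
    atom: str
    prob: float

    def __post_init__(self):
        if not 0.0 <= self.prob <= 1.0:
            raise ProgramError(f"probability of {self.atom!r} outside [0, 1]: {self.prob}")


@dataclass(frozen=True)
class Clause:
    head: str
    body: tuple[str, ...]

    def __post_init__(self):
        if len(self.body) == 0:
            raise ProgramError(f"clause for {self.head!r} has an empty body")


@dataclass
class ProbProgram:
    """Independent probabilistic facts plus definite clauses."""

    facts: list[ProbFact] = field(default_factory=list)
    clauses: list[Clause] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        fact_atoms = [f.atom for f in self.facts]
        if len(set(fact_atoms)) != len(fact_atoms):
            dup = sorted({a for a in fact_atoms if fact_atoms.count(a) > 1})
            raise ProgramError(f"duplicate probabilistic fact atom(s): {dup}")
        fact_set = set(fact_atoms)
        heads = {c.head for c in self.clauses}
        clash = fact_set & heads
        if clash:
            raise ProgramError(f"clause head(s) coincide with fact atom(s): {sorted(clash)}")
        known = fact_set | heads
        for c in self.clauses:
            for atom in c.body:
                if atom not in known:
                    raise ProgramError(
                        f"clause {c.head!r} uses undeclared atom {atom!r}"
                    )
        self._check_acyclic(heads)

    def _check_acyclic(self, heads: set[str]) -> None:
        deps = {h: set() for h in heads}
        for c in self.clauses:
            deps[c.head].update(a for a in c.body if a in heads)
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(node, stack):
            if state.get(node) == 1:
                return
            if state.get(node) == 0:
                raise ProgramError(
                    f"cyclic dependency through {node!r}: {' -> '.join(stack + [node])}"
                )
            state[node] = 0
            for nxt in deps[node]:
                visit(nxt, stack + [node])
            state[node] = 1

        for h in heads:
            visit(h, [])

    # -- semantics -------------------------------------------------------

    @property
    def atoms(self) -> set[str]:
        return {f.atom for f in self.facts} | {c.head for c in self.clauses}

    def derivable(self, atom: str, true_facts: frozenset[str]) -> bool:
        """Least-model derivability of ``atom`` given the facts true in a world."""
        derived = set(true_facts)
        changed = True
        while changed:
            changed = False
            for c in self.clauses:
                if c.head not in derived and all(a in derived for a in c.body):
                    derived.add(c.head)
                    changed = True
        return atom in derived

    def query(self, atom: str) -> float:
        """Exact marginal probability that ``atom`` is derivable.

        Shannon expansion: condition on one fact at a time, pruning branches
        where the atom is already derivable from the facts fixed true
        (contributes the full remaining weight) or cannot be derived even if
        every remaining fact were true (contributes zero).
        """
        if atom not in self.atoms:
            raise KeyError(f"unknown atom {atom!r}")
        fact_list = list(self.facts)

        def expand(i: int, fixed_true: frozenset[str]) -> float:
            if self.derivable(atom, fixed_true):
                return 1.0
            optimistic = fixed_true | {f.atom for f in fact_list[i:]}
            if not self.derivable(atom, frozenset(optimistic)):
                return 0.0
            f = fact_list[i]
            return f.prob * expand(i + 1, fixed_true | {f.atom}) + (
                1.0 - f.prob
            ) * expand(i + 1, fixed_true)

        return expand(0, frozenset())

    def enumerate_worlds(self, cap: int = DEFAULT_WORLD_CAP) -> list[tuple[dict, float]]:
        """All possible worlds with their weights (brute-force oracle).

        Returns ``2^|facts|`` pairs of (fact-truth assignment, weight); the
        weights multiply the independent fact probabilities and sum to 1.
        """
        n = len(self.facts)
        if n > cap:
            raise ProgramError(
                f"program has {n} facts; world enumeration is capped at {cap} "
                "(raise the cap explicitly if you really want 2^n worlds)"
            )
        worlds = []
        for bits in range(2**n):
            assignment = {}
            weight = 1.0
            for k, f in enumerate(self.facts):
                true = bool((bits >> k) & 1)
                assignment[f.atom] = true
                weight *= f.prob if true else 1.0 - f.prob
            worlds.append((assignment, weight))
        return worlds

    def query_by_enumeration(self, atom: str, cap: int = DEFAULT_WORLD_CAP) -> float:
        """Marginal via full world enumeration (independent oracle route)."""
        if atom not in self.atoms:
            raise KeyError(f"unknown atom {atom!r}")
        total = 0.0
        for assignment, weight in self.enumerate_worlds(cap):
            true_facts = frozenset(a for a, t in assignment.items() if t)
            if self.derivable(atom, true_facts):
                total += weight
        return total

    # -- rendering -------------------------------------------------------

    def render(self) -> str:
        lines = [f"{f.prob}::{f.atom}." for f in self.facts]
        lines += [f"{c.head} :- {', '.join(c.body)}." for c in self.clauses]
        return "\n".join(lines) + "\n"


_FACT_RE = re.compile(r"^\s*([01]?\.?\d*(?:[eE][+-]?\d+)?)\s*::\s*([a-z]\w*)\s*\.\s*$")
_CLAUSE_RE = re.compile(r"^\s*([a-z]\w*)\s*:-\s*(.+?)\s*\.\s*$")
_ATOM_RE = re.compile(r"^[a-z]\w*$")


def parse_program(text: str) -> ProbProgram:
    """Parse the mini-syntax: ``0.9::fever.`` facts, ``h :- a, b.`` clauses.

    ``%`` starts a comment; blank lines are ignored. Errors carry the line
    number. The parsed program is validated (duplicates, undeclared atoms,
    cycles).
    """
    facts: list[ProbFact] = []
    clauses: list[Clause] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("%", 1)[0].strip()
        if not line:
            continue
        m = _FACT_RE.match(line)
        if m:
            try:
                prob = float(m.group(1))
            except ValueError:
                raise ProgramError(f"line {lineno}: bad probability {m.group(1)!r}")
            facts.append(ProbFact(m.group(2), prob))
            continue
        m = _CLAUSE_RE.match(line)
        if m:
            body = tuple(a.strip() for a in m.group(2).split(","))
            for a in body:
                if not _ATOM_RE.match(a):
                    raise ProgramError(f"line {lineno}: bad atom {a!r}")
            clauses.append(Clause(m.group(1), body))
            continue
        raise ProgramError(f"line {lineno}: cannot parse {line!r}")
    try:
        return ProbProgram(facts, clauses)
    except ProgramError as e:
        raise ProgramError(str(e)) from None


def load_example(name: str = "sars_call") -> ProbProgram:
    """Load a shipped example program by name (e.g. ``sars_call``)."""
    from importlib import resources

    ref = resources.files("sarsmon") / "examples" / f"{name}.pl"
    try:
        return parse_program(ref.read_text())
    except FileNotFoundError:
        raise ValueError(f"unknown example program {name!r}") from None


def query(program: ProbProgram, atom: str) -> float:
    """Functional wrapper over :meth:`ProbProgram.query`."""
    return program.query(atom)


def enumerate_worlds(program: ProbProgram, cap: int = DEFAULT_WORLD_CAP):
    """Functional wrapper over :meth:`ProbProgram.enumerate_worlds`."""
    return program.enumerate_worlds(cap)
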