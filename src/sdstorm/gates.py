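"""DNA strand-displacement gates: parsing, structural verification, orthogonality.

A strand-displacement gate is a protector/template duplex engineered with an
exposed single-stranded toehold on the template.  The dye-carrying template
hybridizes to the antibody-conjugated protector; a full-length-complementary
invader strand nucleates at the toehold and displaces the template by branch
migration, carrying the dye away as inert waste.

This module verifies the structural facts of such gates directly from the
printed sequences — duplex length, toehold position and length, full invader
complementarity — and screens pairs of gate sets for cross-hybridization using
a longest-ungapped-complementary-run score.  Complementarity is strict
Watson-Crick (A·T, G·C); no wobble pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "Strand",
    "GateSet",
    "DuplexSegment",
    "GateCheck",
    "ValidationReport",
    "CrossReactivityReport",
    "reverse_complement",
    "duplex_map",
    "longest_complementary_run",
    "toehold_of",
    "verify_gate",
    "cross_reactivity",
    "parse_gate_file",
    "set_a",
    "set_b",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

# IDT-style modification tokens, e.g. /5Alex647N/ ... /3AzideN/
_MOD_TOKEN = re.compile(r"/([0-9A-Za-z._-]+)/")


class InvalidAlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T}."""


class ZeroLengthToeholdError(ValueError):
    """The protector fully covers the template: no toehold exists, so the
    gate cannot support toehold-mediated strand displacement."""


def _canonical(sequence: str) -> str:
    """Upper-case a sequence and reject anything outside A/C/G/T (DNA only;
    U is rejected)."""
    seq = sequence.strip().upper()
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise InvalidAlphabetError(
                f"invalid character {ch!r} at position {i} (expected A/C/G/T)"
            )
    return seq


def reverse_complement(sequence: str) -> str:
    """Antiparallel Watson-Crick complement, returned 5'->3'.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    return _canonical(sequence).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Strand:
    """A single DNA strand, stored 5'->3'.

    ``linker`` is a short non-hybridizing 3' extension (e.g. the "TT" spacer
    preceding the azide on a protector); it is excluded from every
    complementarity computation.  Modifications (dye, azide) are carried as
    plain-text fields and never enter sequence arithmetic.
    """

    name: str
    role: str  # "protector" | "template" | "invader"
    sequence: str
    five_prime_mod: str | None = None
    three_prime_mod: str | None = None
    linker: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _canonical(self.sequence))
        if self.linker is not None:
            object.__setattr__(self, "linker", _canonical(self.linker))
        if len(self.sequence) < 1:
            raise ValueError(f"strand {self.name!r}: empty sequence")
        if self.role not in ("protector", "template", "invader"):
            raise ValueError(f"strand {self.name!r}: unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def full_sequence(self) -> str:
        """Hybridizing sequence plus linker, as synthesized (5'->3')."""
        return self.sequence + (self.linker or "")


@dataclass(frozen=True)
class DuplexSegment:
    """A contiguous stretch of one strand, 0-based half-open on the 5'->3'
    sequence."""

    strand_name: str
    start: int
    end: int
    segment_sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")
        if len(self.segment_sequence) != self.end - self.start:
            raise ValueError("segment_sequence length must equal end - start")

    @property
    def length(self) -> int:
        return self.end - self.start


def duplex_map(a: Strand | str, b: Strand | str) -> tuple[int, list[tuple[int, int]]]:
    """Maximal ungapped antiparallel Watson-Crick alignment of two strands.

    Slides the two strands against each other at every relative offset (no
    gaps) and returns ``(paired_count, alignment)`` for the offset with the
    most Watson-Crick pairs; ``alignment`` lists ``(i, j)`` index pairs
    (0-based, each strand's own 5'->3' coordinates).  In an ungapped
    antiparallel alignment all pairs share a constant ``i + j``.

    Ties are broken by the smallest absolute offset between the 5' ends of
    ``a`` and of ``reverse_complement(b)``, then by the 5'-most start on
    ``a``.  Linkers, when present, are excluded.
    """
    sa = a.sequence if isinstance(a, Strand) else _canonical(a)
    sb = b.sequence if isinstance(b, Strand) else _canonical(b)
    la, lb = len(sa), len(sb)
    comp_b = sb.translate(_COMPLEMENT)  # comp_b[j] pairs sa[i] iff equal

    best: tuple[int, int, int] | None = None  # (-count, |offset|, start_a)
    best_pairs: list[tuple[int, int]] = []
    for s in range(la + lb - 1):  # diagonal: i + j == s
        pairs = [
            (i, s - i)
            for i in range(max(0, s - lb + 1), min(la, s + 1))
            if sa[i] == comp_b[s - i]
        ]
        if not pairs:
            continue
        offset = s - (lb - 1)  # shift of a relative to reverse_complement(b)
        key = (-len(pairs), abs(offset), pairs[0][0])
        if best is None or key < best:
            best, best_pairs = key, pairs
    if best is None:
        return 0, []
    return -best[0], best_pairs


def longest_complementary_run(a: Strand | str, b: Strand | str) -> tuple[int, list[tuple[int, int]]]:
    """Longest run of consecutive antiparallel Watson-Crick pairs between two
    strands, over all ungapped offsets.

    Returns ``(run_length, positions)`` where positions are the ``(i, j)``
    pairs of the first-found maximal run (scanning diagonals 5'->3' on ``a``).
    """
    sa = a.sequence if isinstance(a, Strand) else _canonical(a)
    sb = b.sequence if isinstance(b, Strand) else _canonical(b)
    la, lb = len(sa), len(sb)
    comp_b = sb.translate(_COMPLEMENT)

    best_len = 0
    best_pos: list[tuple[int, int]] = []
    for s in range(la + lb - 1):
        run_start = None
        i0 = max(0, s - lb + 1)
        for i in range(i0, min(la, s + 1) + 1):
            matched = i < min(la, s + 1) and sa[i] == comp_b[s - i]
            if matched and run_start is None:
                run_start = i
            elif not matched and run_start is not None:
                if i - run_start > best_len:
                    best_len = i - run_start
                    best_pos = [(k, s - k) for k in range(run_start, i)]
                run_start = None
    return best_len, best_pos


@dataclass(frozen=True)
class GateSet:
    """A named protector/template/invader triple with derived duplex and
    toehold structure.

    ``duplex_length`` is the paired-base count of the maximal ungapped
    antiparallel alignment of template vs protector; the toehold is the
    contiguous template region the protector leaves single-stranded.
    """

    name: str
    protector: Strand
    template: Strand
    invader: Strand
    duplex_length: int = field(init=False)
    toehold: DuplexSegment = field(init=False)

    def __post_init__(self) -> None:
        count, pairs = duplex_map(self.template, self.protector)
        object.__setattr__(self, "duplex_length", count)
        object.__setattr__(self, "toehold", _toehold_segment(self.template, pairs))

    @property
    def strands(self) -> tuple[Strand, Strand, Strand]:
        return (self.protector, self.template, self.invader)


def _toehold_segment(template: Strand, duplex_pairs: list[tuple[int, int]]) -> DuplexSegment:
    """Contiguous template region left unpaired by the protector."""
    paired = {i for i, _ in duplex_pairs}
    unpaired = [i for i in range(len(template)) if i not in paired]
    if not unpaired:
        raise ZeroLengthToeholdError(
            f"template {template.name!r} is fully paired by the protector: "
            "no toehold for strand displacement"
        )
    start, end = unpaired[0], unpaired[-1] + 1
    if end - start != len(unpaired):
        raise ValueError(
            f"template {template.name!r}: unpaired region is not contiguous"
        )
    return DuplexSegment(
        strand_name=template.name,
        start=start,
        end=end,
        segment_sequence=template.sequence[start:end],
    )


def toehold_of(gate: GateSet) -> DuplexSegment:
    """The gate's toehold: the single-stranded template overhang where the
    invader nucleates.  For both built-in sets this is the template's
    3'-terminal 8 nucleotides."""
    return gate.toehold


@dataclass(frozen=True)
class GateCheck:
    name: str
    passed: bool
    observed: object
    expected: object
    message: str


@dataclass(frozen=True)
class ValidationReport:
    gate_name: str
    checks: tuple[GateCheck, ...]

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __iter__(self):
        return iter(self.checks)


def verify_gate(
    gate: GateSet,
    *,
    template_length: int = 38,
    protector_length: int = 30,
    duplex_length: int = 30,
) -> ValidationReport:
    """Run the structural checks that define a working displacement gate.

    Checks, in order: template length, protector hybridizing length, duplex
    length, toehold length > 0, invader is the full reverse complement of the
    template, and the invader 5' end complements the toehold (so a nucleation
    region exists).  Failures are report entries, never exceptions.  The
    expected lengths default to the 38/30/30 design of the built-in sets but
    are parameters, not constants.
    """
    checks: list[GateCheck] = []

    def add(name, passed, observed, expected, message):
        checks.append(GateCheck(name, bool(passed), observed, expected, message))

    tl = len(gate.template)
    add("template_length", tl == template_length, tl, template_length,
        f"template is {tl} nt")
    pl = len(gate.protector)
    add("protector_length", pl == protector_length, pl, protector_length,
        f"protector hybridizing region is {pl} nt (linker excluded)")
    add("duplex_length", gate.duplex_length == duplex_length,
        gate.duplex_length, duplex_length,
        f"template/protector duplex is {gate.duplex_length} bp")
    th = gate.toehold.length
    add("toehold_nonzero", th > 0, th, "> 0",
        f"toehold is {th} nt ({gate.toehold.segment_sequence})")
    inv_pairs, _ = duplex_map(gate.invader, gate.template)
    add("invader_full_complement", inv_pairs == tl, inv_pairs, tl,
        f"invader pairs {inv_pairs} of {tl} template positions")
    # The invader's 5'-terminal bases must pair the toehold so displacement
    # can nucleate before branch migration.
    nuc = reverse_complement(gate.toehold.segment_sequence)
    has_nucleation = gate.invader.sequence.startswith(nuc)
    add("toehold_nucleation", has_nucleation,
        gate.invader.sequence[: th], nuc,
        "invader 5' end complements the toehold" if has_nucleation
        else "invader 5' end does not complement the toehold")
    return ValidationReport(gate_name=gate.name, checks=tuple(checks))


@dataclass(frozen=True)
class PairScore:
    strand_a: str
    strand_b: str
    longest_complementary_run: int
    run_positions: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class CrossReactivityReport:
    """Orthogonality screen between two gate sets.

    ``max_run`` is the longest ungapped antiparallel Watson-Crick run over
    all 9 inter-set strand pairs; sets are classified orthogonal when
    ``max_run < threshold``.  The run-length score is an explicit sequence-level
    stand-in for a thermodynamic orthogonality criterion; the threshold is
    always reported, never silent.
    """

    set_a: str
    set_b: str
    per_pair_scores: tuple[PairScore, ...]
    max_run: int
    threshold: int
    same_set_warning: bool = False

    @property
    def orthogonal(self) -> bool:
        return self.max_run < self.threshold


def cross_reactivity(
    set_a: GateSet, set_b: GateSet, *, threshold: int = 10
) -> CrossReactivityReport:
    """Screen every inter-set strand pair for cross-hybridization potential.

    Comparing a set with itself is flagged with a warning rather than an
    error: intra-set pairs are complementary by design (the template/invader
    pair scores the full template length).
    """
    scores = []
    for a in set_a.strands:
        for b in set_b.strands:
            run, pos = longest_complementary_run(a, b)
            scores.append(PairScore(a.name, b.name, run, tuple(pos)))
    return CrossReactivityReport(
        set_a=set_a.name,
        set_b=set_b.name,
        per_pair_scores=tuple(scores),
        max_run=max(s.longest_complementary_run for s in scores),
        threshold=threshold,
        same_set_warning=(set_a.name == set_b.name),
    )


def _strip_mods(raw: str) -> tuple[str, str | None, str | None]:
    """Split IDT-style modification tokens off a raw sequence string.

    ``/5.../`` tokens (or any token before the first base) become the 5'
    modification; tokens after the last base become the 3' modification.
    Whitespace is ignored.
    """
    raw = raw.strip()
    five = three = None
    m = _MOD_TOKEN.match(raw)
    if m:
        five = m.group(1)
        raw = raw[m.end():]
    m = _MOD_TOKEN.search(raw)
    if m and raw.endswith("/"):
        # token at the 3' end
        last = None
        for last in _MOD_TOKEN.finditer(raw):
            pass
        if last is not None and last.end() == len(raw):
            three = last.group(1)
            raw = raw[: last.start()]
    return "".join(raw.split()), five, three


def parse_gate_file(
    path_or_lines: str | Iterable[str], *, protector_linker: str = "TT"
) -> dict[str, GateSet]:
    """Read gate sets from a FASTA-like text file.

    Record names encode set and role (``>A_protector``, ``>A_template``,
    ``>A_invader``).  IDT-style modification tokens (``/5Alex647N/``,
    ``/3AzideN/``) are accepted anywhere in the sequence line and stored as
    modification fields.  A protector sequence ending in ``protector_linker``
    has that suffix split off as a non-hybridizing 3' linker (pass
    ``protector_linker=""`` to disable).
    """
    if isinstance(path_or_lines, str):
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
    else:
        lines = [str(l) for l in path_or_lines]

    records: dict[str, str] = {}
    current: str | None = None
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            current = line[1:].strip()
            records[current] = ""
        elif current is not None:
            records[current] += line
        else:
            raise ValueError("sequence data before first '>' header")

    strands: dict[str, dict[str, Strand]] = {}
    for name, raw in records.items():
        try:
            set_name, role = name.rsplit("_", 1)
        except ValueError:
            raise ValueError(
                f"record name {name!r} must look like '<set>_<role>'"
            ) from None
        role = role.lower()
        seq, five, three = _strip_mods(raw)
        linker = None
        if role == "protector" and protector_linker and seq.upper().endswith(
            protector_linker.upper()
        ):
            seq, linker = seq[: -len(protector_linker)], protector_linker
        strands.setdefault(set_name, {})[role] = Strand(
            name=name, role=role, sequence=seq,
            five_prime_mod=five, three_prime_mod=three, linker=linker,
        )

    gates: dict[str, GateSet] = {}
    for set_name, parts in strands.items():
        missing = {"protector", "template", "invader"} - parts.keys()
        if missing:
            raise ValueError(f"set {set_name!r} is missing roles: {sorted(missing)}")
        gates[set_name] = GateSet(
            name=set_name,
            protector=parts["protector"],
            template=parts["template"],
            invader=parts["invader"],
        )
    return gates


# ---------------------------------------------------------------------------
# The two published orthogonal gate sets (sequences 5'->3'; the protector
# carries a non-hybridizing 3' "TT" spacer before its azide).

_SET_A = {
    "protector": ("GCCTGCTTTATCTCTGTTCTACTATTTCCG", "TT", None, "AzideN"),
    "template": ("CGGAAATAGTAGAACAGAGATAAAGCAGGCAAACGAAA", None, "Alex647N", None),
    "invader": ("TTTCGTTTGCCTGCTTTATCTCTGTTCTACTATTTCCG", None, None, None),
}
_SET_B = {
    "protector": ("GGGTCAAGTCAAAGTCAAGTATCAAGTCGG", "TT", None, "AzideN"),
    "template": ("CCGACTTGATACTTGACTTTGACTTGACCCTTGATATT", None, "Alex647N", None),
    "invader": ("AATATCAAGGGTCAAGTCAAAGTCAAGTATCAAGTCGG", None, None, None),
}


def _build(name: str, spec: dict) -> GateSet:
    strands = {
        role: Strand(
            name=f"{name}_{role}", role=role, sequence=seq,
            linker=linker, five_prime_mod=five, three_prime_mod=three,
        )
        for role, (seq, linker, five, three) in spec.items()
    }
    return GateSet(name=name, **strands)


def set_a() -> GateSet:
    """Built-in gate Set A (38-nt template, 30-bp duplex, 8-nt toehold)."""
    return _build("A", _SET_A)


def set_b() -> GateSet:
    """Built-in gate Set B, orthogonal to Set A."""
    return _build("B", _SET_B)
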