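"""Promoter parts, architectures, and combinatorial −35 × −10 libraries.

A bacterial σ70 promoter is assembled here from modular parts: an operator
for a ligand-inducible activator immediately upstream of the −35 hexamer,
an optional repressor operator in the spacer (or at +1 / far upstream), the
−35 and −10 hexamers themselves, and a fixed downstream reporter context.
Promoter strength is dominated by the −35/−10 sequences, so the library is
the full Cartesian product of a −35 list and a −10 list.

Coordinates are 0-based offsets relative to the +1 transcription start;
negative = upstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical E. coli σ70 hexamer consensus sequences.
CONSENSUS_MINUS35 = "TTGACA"
CONSENSUS_MINUS10 = "TATAAT"

_VALID_BASES = frozenset("ACGT")
SITE_LENGTH = 6


class LibraryError(ValueError):
    """Invalid promoter part, architecture, or library definition."""


@dataclass(frozen=True)
class PromoterPart:
    """A −35 or −10 hexamer.

    Labels follow the lowercase-(−35) / uppercase-(−10) convention, so a
    variant id like ``dE`` reads as −35 site "d" with −10 site "E".
    """

    label: str
    kind: str  # "minus35" | "minus10"
    sequence: str

    def __post_init__(self) -> None:
        if self.kind not in ("minus35", "minus10"):
            raise LibraryError(f"unknown part kind {self.kind!r}")
        seq = self.sequence.upper()
        if len(seq) != SITE_LENGTH or not set(seq) <= _VALID_BASES:
            raise LibraryError(
                f"part {self.label!r}: sequence must be {SITE_LENGTH} bases "
                f"over ACGT, got {self.sequence!r}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def consensus(self) -> str:
        return CONSENSUS_MINUS35 if self.kind == "minus35" else CONSENSUS_MINUS10


@dataclass(frozen=True)
class OperatorSite:
    """A transcription-factor operator at a signed offset from +1."""

    name: str
    role: str  # "activator" | "repressor"
    position: int
    sequence: str = "N" * 20  # symbolic placeholder; base content is never read

    def __post_init__(self) -> None:
        if self.role not in ("activator", "repressor"):
            raise LibraryError(f"operator {self.name!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class PromoterArchitecture:
    """Layout of operators around the −35/−10 core.

    Exactly one activator operator sits immediately upstream of the −35
    site; repressor operators may sit in the spacer, at +1, or far upstream.
    """

    activator_operator: OperatorSite
    spacer_operators: tuple[OperatorSite, ...] = ()
    auxiliary_operators: tuple[OperatorSite, ...] = ()
    reporter: str = "yfp"

    def __post_init__(self) -> None:
        if self.activator_operator.role != "activator":
            raise LibraryError("activator_operator must have role 'activator'")
        for op in (*self.spacer_operators, *self.auxiliary_operators):
            if op.role != "repressor":
                raise LibraryError(
                    f"operator {op.name!r} in a repressor slot must have role "
                    "'repressor'"
                )
        object.__setattr__(self, "spacer_operators", tuple(self.spacer_operators))
        object.__setattr__(self, "auxiliary_operators", tuple(self.auxiliary_operators))

    @property
    def activator_name(self) -> str:
        return self.activator_operator.name


@dataclass(frozen=True)
class PromoterVariant:
    """One concrete promoter: architecture + a (−35, −10) part pair."""

    architecture: PromoterArchitecture
    minus35: PromoterPart
    minus10: PromoterPart

    def __post_init__(self) -> None:
        if self.minus35.kind != "minus35" or self.minus10.kind != "minus10":
            raise LibraryError("variant parts must be a minus35 and a minus10 site")

    @property
    def id(self) -> str:
        """Deterministic id ``<activator>-<m35 label><m10 label>``, e.g. ``ara-dE``."""
        act = self.architecture.activator_name.lower()
        return f"{act}-{self.minus35.label}{self.minus10.label}"

    @property
    def core_label(self) -> str:
        """The bare −35/−10 combination label, e.g. ``dE``."""
        return f"{self.minus35.label}{self.minus10.label}"


def parse_variant_id(variant_id: str) -> tuple[str, str, str]:
    """Split ``<activator>-<m35><m10>`` into (activator, m35 label, m10 label)."""
    head, _, core = variant_id.rpartition("-")
    if not head or len(core) < 2:
        raise LibraryError(f"malformed variant id {variant_id!r}")
    return head, core[:-1], core[-1:]


def _check_unique_labels(parts: Sequence[PromoterPart], kind: str) -> None:
    seen: set[str] = set()
    for p in parts:
        if p.kind != kind:
            raise LibraryError(f"part {p.label!r} has kind {p.kind}, expected {kind}")
        if p.label in seen:
            raise LibraryError(f"duplicate {kind} label {p.label!r}")
        seen.add(p.label)


def assemble_library(
    minus35_list: Sequence[PromoterPart],
    minus10_list: Sequence[PromoterPart],
    architecture: PromoterArchitecture,
) -> list[PromoterVariant]:
    """Full Cartesian product of −35 and −10 parts under one architecture.

    Deterministic order: −35 outer, −10 inner, each sorted alphabetically
    by label. Size is ``len(minus35_list) * len(minus10_list)``.
    """
    _check_unique_labels(minus35_list, "minus35")
    _check_unique_labels(minus10_list, "minus10")
    m35 = sorted(minus35_list, key=lambda p: p.label)
    m10 = sorted(minus10_list, key=lambda p: p.label)
    return [
        PromoterVariant(architecture=architecture, minus35=a, minus10=b)
        for a, b in itertools.product(m35, m10)
    ]


def mismatch_count(site: PromoterPart, consensus: str | None = None) -> int:
    """Hamming distance between a site and its consensus hexamer.

    With no explicit consensus, the canonical σ70 consensus for the site's
    kind is used (TTGACA for −35, TATAAT for −10).
    """
    ref = (consensus or site.consensus).upper()
    if len(ref) != len(site.sequence):
        raise LibraryError(
            f"consensus length {len(ref)} != site length {len(site.sequence)}"
        )
    return sum(a != b for a, b in zip(site.sequence, ref))


def substitute_base(site: PromoterPart, position: int, base: str) -> PromoterPart:
    """Point-substitute one base; the label gains a ``*`` to mark the variant.

    Substituting a base with itself returns an equal-sequence part (still
    relabelled), mirroring e.g. the d (TTTACA) → d* (TTTACT) modification.
    """
    if not 0 <= position < SITE_LENGTH:
        raise LibraryError(f"position {position} out of range [0, {SITE_LENGTH})")
    base = base.upper()
    if base not in _VALID_BASES:
        raise LibraryError(f"invalid base {base!r}")
    seq = site.sequence[:position] + base + site.sequence[position + 1 :]
    return replace(site, label=site.label + "*", sequence=seq)


def variant_sequence(variant: PromoterVariant, spacer: str = "N" * 17) -> str:
    """Linear sequence sketch: activator operator, −35, spacer (with any
    repressor operators left symbolic), −10, reporter tag."""
    arch = variant.architecture
    pieces = [arch.activator_operator.sequence, variant.minus35.sequence, spacer,
              variant.minus10.sequence]
    return "".join(pieces)


def export_fasta(library: Iterable[PromoterVariant], path: str | Path) -> Path:
    """Write one FASTA record per variant (header = variant id)."""
    records = [
        SeqRecord(Seq(variant_sequence(v)), id=v.id, description="")
        for v in library
    ]
    path = Path(path)
    SeqIO.write(records, str(path), "fasta")
    return path


def read_parts_csv(path: str | Path) -> list[PromoterPart]:
    """Read a part list from CSV with columns label,kind,sequence."""
    df = pd.read_csv(path)
    missing = {"label", "kind", "sequence"} - set(df.columns)
    if missing:
        raise LibraryError(f"parts CSV missing columns: {sorted(missing)}")
    return [
        PromoterPart(label=str(r.label), kind=str(r.kind), sequence=str(r.sequence))
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------------
# Packaged fixture library: 6 −35 sites (a–f) × 8 −10 sites (A–H) = 48
# combinations. Only d (TTTACA), its modified form d* (TTTACT), E (GATACT)
# and F (GATAAT) are published sequences; every other sequence below is a
# synthetic placeholder with a plausible mismatch count and carries no
# experimental meaning.
# --------------------------------------------------------------------------

FIXTURE_MINUS35: tuple[PromoterPart, ...] = (
    PromoterPart("a", "minus35", "TTGACA"),  # consensus
    PromoterPart("b", "minus35", "TTGACT"),  # placeholder
    PromoterPart("c", "minus35", "TTGATA"),  # placeholder
    PromoterPart("d", "minus35", "TTTACA"),  # published medium-affinity site
    PromoterPart("e", "minus35", "TTCACC"),  # placeholder
    PromoterPart("f", "minus35", "CTGACG"),  # placeholder
)

FIXTURE_MINUS10: tuple[PromoterPart, ...] = (
    PromoterPart("A", "minus10", "TATAAT"),  # consensus
    PromoterPart("B", "minus10", "TATACT"),  # placeholder
    PromoterPart("C", "minus10", "CATAAT"),  # placeholder
    PromoterPart("D", "minus10", "TATGAT"),  # placeholder
    PromoterPart("E", "minus10", "GATACT"),  # published (lower leak/signal)
    PromoterPart("F", "minus10", "GATAAT"),  # published (higher leak/signal)
    PromoterPart("G", "minus10", "TACAAT"),  # placeholder
    PromoterPart("H", "minus10", "CCTAAT"),  # placeholder
)


def default_architecture(activator: str = "ara") -> PromoterArchitecture:
    """AraC-style architecture: proximal activator operator, LacO1 spacer site."""
    return PromoterArchitecture(
        activator_operator=OperatorSite(activator, "activator", position=-60),
        spacer_operators=(OperatorSite("LacO1", "repressor", position=-20),),
    )


def fixture_library(activator: str = "ara") -> list[PromoterVariant]:
    """The packaged 48-member combinatorial library."""
    return assemble_library(
        list(FIXTURE_MINUS35), list(FIXTURE_MINUS10), default_architecture(activator)
    )
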