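"""Germline recombination signal sequences (RSSs) of human IGHJ and IGHD genes.

An RSS is the conserved motif flanking every V, D and J gene segment: a
7-mer (heptamer) abutting the coding region, a spacer of nominally 12 or
23 bp, and a 9-mer (nonamer).  The RAG recombinase joins a 12-spacer RSS
to a 23-spacer RSS (the 12/23 rule), so D-J joining pairs the 23-spacer
RSS upstream of a J segment with the 12-spacer RSS downstream of a D
segment.

All stored J-side elements use the coding-strand-complement convention in
which the nonamer consensus reads ``CCAAAAACA`` and the heptamer consensus
``CACAGTG``; positional substitutions within an element use 1-based
IMGT-style labels (``9-4G`` = nonamer position 4 substituted to G).  The
``GGTTTTTGT``/``GTGTCAC`` representation is the plain complement and is
derived on demand, never stored.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .errors import (
    CompositionUnavailable,
    ConfigError,
    ConsistencyError,
    NoRSSFound,
    StructuralError,
)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
#: Watson-Crick pairs; N never pairs.
_WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


def complement(seq: str) -> str:
    """Base-by-base complement, preserving 5'→3' position numbering."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


class Side(str, Enum):
    """Which flank of which segment class an RSS sits on.

    The three numbers name the element order read away from the coding
    region and the nominal spacer length, e.g. ``9_23_7`` = nonamer,
    23 bp spacer, heptamer adjacent to the coding edge.
    """

    J_UPSTREAM = "J_upstream_9_23_7"
    D_DOWNSTREAM = "D_downstream_9_12_7"
    D_UPSTREAM = "D_upstream_7_12_9"
    V_DOWNSTREAM = "V_downstream_7_23_9"


NOMINAL_SPACER: dict[Side, int] = {
    Side.J_UPSTREAM: 23,
    Side.V_DOWNSTREAM: 23,
    Side.D_DOWNSTREAM: 12,
    Side.D_UPSTREAM: 12,
}

SPACER_LENGTH_RANGE = (11, 24)


def _check_dna(seq: str, what: str, owner: str = "") -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        where = f" of {owner}" if owner else ""
        raise ConfigError(f"{what}{where} contains non-DNA letters {sorted(bad)!r}")


@dataclass(frozen=True)
class RSS:
    """One recombination signal sequence, stored on the printed-top-strand convention."""

    gene_name: str
    side: Side
    nonamer: str
    heptamer: str
    spacer_length: int
    spacer: str | None = None  # sequence when known, else declared-length-only
    strand_convention: str = "as_printed_top"
    discrepancies: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.nonamer) != 9:
            raise ConfigError(
                f"nonamer of {self.gene_name} has length {len(self.nonamer)}, expected 9"
            )
        if len(self.heptamer) != 7:
            raise ConfigError(
                f"heptamer of {self.gene_name} has length {len(self.heptamer)}, expected 7"
            )
        _check_dna(self.nonamer, "nonamer", self.gene_name)
        _check_dna(self.heptamer, "heptamer", self.gene_name)
        lo, hi = SPACER_LENGTH_RANGE
        if not lo <= self.spacer_length <= hi:
            raise ConfigError(
                f"spacer length {self.spacer_length} of {self.gene_name} outside [{lo}, {hi}]"
            )
        if self.spacer is not None:
            _check_dna(self.spacer, "spacer", self.gene_name)
            if len(self.spacer) != self.spacer_length:
                raise ConfigError(
                    f"spacer sequence of {self.gene_name} has length {len(self.spacer)}, "
                    f"declared {self.spacer_length}"
                )

    @property
    def nominal_spacer_length(self) -> int:
        return NOMINAL_SPACER[self.side]

    def complemented(self) -> "RSS":
        """The same RSS on the opposite strand (plain complement, positions preserved)."""
        return replace(
            self,
            nonamer=complement(self.nonamer),
            heptamer=complement(self.heptamer),
            spacer=None if self.spacer is None else complement(self.spacer),
            strand_convention=(
                "complement" if self.strand_convention == "as_printed_top" else "as_printed_top"
            ),
        )


@dataclass(frozen=True)
class ConsensusSet:
    """Consensus RSS elements on the stored strand convention."""

    j_nonamer: str = "CCAAAAACA"
    heptamer: str = "CACAGTG"
    d_nonamer: str = "ACAAAAACC"
    nominal_spacer_j: int = 23
    nominal_spacer_d: int = 12

    @property
    def j_nonamer_complement(self) -> str:  # GGTTTTTGT
        return complement(self.j_nonamer)

    @property
    def heptamer_complement(self) -> str:  # GTGTCAC
        return complement(self.heptamer)

    def nonamer_for(self, side: Side) -> str:
        return self.j_nonamer if side in (Side.J_UPSTREAM, Side.V_DOWNSTREAM) else self.d_nonamer


#: Alternate J nonamer consensus printed once in an evolutionary context
#: (GGTTTTTTT / CCAAAAAAA); not the packaged default.
ALTERNATE_J_NONAMER = "CCAAAAAAA"

_ELEMENT_PREFIX = {"nonamer": 9, "heptamer": 7}


@dataclass(frozen=True)
class MutationSpec:
    """A single positional substitution within an RSS element.

    ``position`` is 1-based within the element, matching the field's
    ``9-x``/``7-x`` labels.  ``consistent`` is False when the recorded
    from-base did not match the consensus (kept, never silently dropped).
    """

    element: str  # "nonamer" | "heptamer" | "spacer_length"
    position: int
    from_base: str
    to_base: str
    consistent: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.element not in ("nonamer", "heptamer", "spacer_length"):
            raise ConfigError(f"unknown RSS element {self.element!r}")
        if self.element in _ELEMENT_PREFIX and not (
            1 <= self.position <= _ELEMENT_PREFIX[self.element]
        ):
            raise ConfigError(
                f"position {self.position} outside the {self.element} "
                f"(1..{_ELEMENT_PREFIX[self.element]})"
            )

    @property
    def key(self) -> str:
        """IMGT-style label, e.g. ``9-4G`` or ``7-5T``."""
        return f"{_ELEMENT_PREFIX[self.element]}-{self.position}{self.to_base}"


@dataclass(frozen=True)
class GermlineGene:
    """A germline segment: its RSS(s), coding length and synthetic coding sequence."""

    name: str
    rss_set: Mapping[Side, RSS]
    coding_length_aa: int = 0
    coding_seq: str | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name.startswith("IGHJ"):
            if set(self.rss_set) != {Side.J_UPSTREAM}:
                raise ConfigError(f"{self.name} must carry exactly one J-upstream RSS")
            if self.coding_length_aa <= 0:
                raise ConfigError(f"{self.name} coding_length_aa must be positive")
        if self.name.startswith("IGHD") and not (
            Side.D_UPSTREAM in self.rss_set and Side.D_DOWNSTREAM in self.rss_set
        ):
            raise ConfigError(f"{self.name} must carry both a 5' and a 3' RSS")

    @property
    def primary_rss(self) -> RSS:
        """The RSS that participates in D-J joining (J upstream / D downstream)."""
        if Side.J_UPSTREAM in self.rss_set:
            return self.rss_set[Side.J_UPSTREAM]
        return self.rss_set[Side.D_DOWNSTREAM]

    @property
    def coding_length_nt(self) -> int:
        if self.coding_seq is not None:
            return len(self.coding_seq)
        return 3 * self.coding_length_aa


def reconstruct_rss(
    consensus: ConsensusSet,
    gene: str,
    mutations: Sequence[MutationSpec],
    spacer_length: int,
    side: Side = Side.J_UPSTREAM,
    spacer: str | None = None,
    strict: bool = True,
) -> RSS:
    """Apply positional substitutions to the consensus elements.

    With ``strict`` (default) a from-base that disagrees with the
    consensus raises :class:`ConsistencyError` carrying both letters;
    with ``strict=False`` the substitution is still applied and the
    disagreement recorded in the returned RSS's ``discrepancies``.
    """
    elements = {
        "nonamer": list(consensus.nonamer_for(side)),
        "heptamer": list(consensus.heptamer),
    }
    notes: list[str] = []
    for mut in mutations:
        if mut.element == "spacer_length":
            continue
        seq = elements[mut.element]
        have = seq[mut.position - 1]
        if mut.from_base != have:
            msg = (
                f"{gene} {mut.element} position {mut.position}: recorded from-base "
                f"{mut.from_base!r} but consensus has {have!r}"
            )
            if strict and mut.consistent:
                raise ConsistencyError(msg, expected=have, found=mut.from_base)
            notes.append(msg)
        seq[mut.position - 1] = mut.to_base
    return RSS(
        gene_name=gene,
        side=side,
        nonamer="".join(elements["nonamer"]),
        heptamer="".join(elements["heptamer"]),
        spacer_length=spacer_length,
        spacer=spacer,
        discrepancies=tuple(notes),
    )


def mismatch_profile(rss: RSS, consensus: ConsensusSet) -> list[MutationSpec]:
    """Positional differences of an RSS from the consensus (inverse of reconstruction).

    Returns the empty list iff both elements equal the consensus.
    """
    out: list[MutationSpec] = []
    for element, seq, ref in (
        ("nonamer", rss.nonamer, consensus.nonamer_for(rss.side)),
        ("heptamer", rss.heptamer, consensus.heptamer),
    ):
        if len(seq) != len(ref):
            raise StructuralError(
                f"{element} length {len(seq)} vs consensus {len(ref)} for {rss.gene_name}"
            )
        for i, (a, b) in enumerate(zip(ref, seq), start=1):
            if a != b:
                out.append(MutationSpec(element, i, from_base=a, to_base=b))
    return out


def arich_core_intact(nonamer: str) -> tuple[bool, int]:
    """Whether the nonamer keeps a run of >= 3 consecutive A residues.

    A tracts in the nonamer promote strand separation during cleavage;
    three consecutive As are the minimum for efficient joining.  N never
    counts as A.  Returns (intact, longest A-run length).
    """
    if len(nonamer) != 9:
        raise StructuralError(f"nonamer length {len(nonamer)}, expected 9")
    longest = max((len(run) for run in re.findall(r"A+", nonamer)), default=0)
    return longest >= 3, longest


def spacer_composition(spacer: str | None) -> dict[str, object]:
    """Per-base counts and AT/GC fractions of a spacer sequence."""
    if spacer is None or spacer == "":
        raise CompositionUnavailable("spacer is declared-length-only; composition unavailable")
    _check_dna(spacer, "spacer")
    counts = {b: spacer.count(b) for b in "ACGT"}
    counts["N"] = spacer.count("N")
    n = len(spacer)
    return {
        "counts": counts,
        "length": n,
        "at_fraction": (counts["A"] + counts["T"]) / n,
        "gc_fraction": (counts["G"] + counts["C"]) / n,
    }


def extract_rss_from_flank(
    flank: str,
    side: Side = Side.J_UPSTREAM,
    search_window: int = 0,
    consensus: ConsensusSet | None = None,
    max_mismatches: int = 6,
    spacer_length_offsets: Iterable[int] = (-2, -1, 0, 1),
) -> tuple[RSS, dict[str, tuple[int, int]]]:
    """Locate the best nonamer/spacer/heptamer decomposition in a flank.

    The flank is read in the stored strand convention with the heptamer
    adjacent to the coding edge (the 3' end of the string); the heptamer
    end may sit up to ``search_window`` bases before that edge.  Over all
    candidate spacer lengths (nominal + each offset) the decomposition
    minimising total nonamer+heptamer mismatches to the consensus wins;
    ties prefer the nominal spacer length, then the shorter spacer, then
    the position closest to the coding edge.  Offsets in the returned
    mapping are 0-based half-open on the input string.
    """
    consensus = consensus or ConsensusSet()
    _check_dna(flank, "flank")
    if len(flank) < 9 + min(SPACER_LENGTH_RANGE) + 7:
        raise StructuralError(f"flank of length {len(flank)} too short to contain an RSS")
    ref_nonamer = consensus.nonamer_for(side)
    ref_heptamer = consensus.heptamer
    nominal = NOMINAL_SPACER[side]
    lo, hi = SPACER_LENGTH_RANGE

    best: tuple[tuple[int, int, int, int], int, int] | None = None  # (rank, spacer_len, hept_end)
    for k in range(search_window + 1):
        hept_end = len(flank) - k
        hept_start = hept_end - 7
        if hept_start < 9 + lo:
            break
        hept = flank[hept_start:hept_end]
        mm_h = sum(a != b for a, b in zip(ref_heptamer, hept))
        for off in spacer_length_offsets:
            slen = nominal + off
            if not lo <= slen <= hi:
                continue
            non_start = hept_start - slen - 9
            if non_start < 0:
                continue
            non = flank[non_start : non_start + 9]
            mm = mm_h + sum(a != b for a, b in zip(ref_nonamer, non))
            rank = (mm, 0 if slen == nominal else 1, slen, k)
            if best is None or rank < best[0]:
                best = (rank, slen, hept_end)
    if best is None or best[0][0] > max_mismatches:
        found = "none" if best is None else f"{best[0][0]} mismatches"
        raise NoRSSFound(f"no RSS decomposition within {max_mismatches} mismatches ({found})")

    _, slen, hept_end = best
    hept_start = hept_end - 7
    non_start = hept_start - slen - 9
    rss = RSS(
        gene_name="extracted",
        side=side,
        nonamer=flank[non_start : non_start + 9],
        heptamer=flank[hept_start:hept_end],
        spacer_length=slen,
        spacer=flank[non_start + 9 : hept_start],
    )
    offsets = {
        "nonamer": (non_start, non_start + 9),
        "spacer": (non_start + 9, hept_start),
        "heptamer": (hept_start, hept_end),
    }
    return rss, offsets


def complementarity_score(rss_a: RSS, rss_b: RSS, element: str = "nonamer") -> float:
    """Fraction of Watson-Crick-paired positions in an antiparallel alignment.

    Element of ``rss_a`` (5'→3') is laid against element of ``rss_b``
    reversed; symmetric in its arguments.  Models the hypothetical
    duplex pairing of a J-side element with a D-side element.
    """
    if element not in ("nonamer", "heptamer"):
        raise StructuralError(f"unknown element {element!r}")
    a = getattr(rss_a, element)
    b = getattr(rss_b, element)
    if len(a) != len(b):
        raise StructuralError(f"{element} length mismatch: {len(a)} vs {len(b)}")
    paired = sum((x, y) in _WC_PAIRS for x, y in zip(a, reversed(b)))
    return paired / len(a)


# ---------------------------------------------------------------------------
# Packaged germline configuration


def synthetic_coding_sequence(name: str, length_nt: int) -> str:
    """Deterministic synthetic coding-region stand-in for a germline segment.

    Real coding sequences are out of scope for the statistics computed
    here (only identities and lengths matter); a per-gene pseudo-random
    sequence keyed on the gene name keeps junctions distinct and runs
    reproducible.
    """
    import zlib

    import numpy as np

    rng = np.random.default_rng(zlib.crc32(name.encode()) & 0x7FFFFFFF)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length_nt)])


def _mutations_from_config(entries: Sequence[Mapping], element: str, gene: str) -> list[MutationSpec]:
    out = []
    for e in entries:
        try:
            out.append(
                MutationSpec(
                    element=element,
                    position=int(e["position"]),
                    from_base=e["frm"],
                    to_base=e["to"],
                    consistent=bool(e.get("consistent", True)),
                    note=e.get("printed", ""),
                )
            )
        except (KeyError, ConfigError) as exc:
            raise ConfigError(f"{gene}: bad {element} mutation entry {e!r}: {exc}") from exc
    return out


def load_germline_config(path_or_default: str = "default") -> dict[str, GermlineGene]:
    """Load the germline catalogue: 6 IGHJ genes and the 27-gene IGHD set.

    ``"default"`` loads the packaged configuration (consensus elements
    plus per-gene substitution lists and spacer lengths); otherwise the
    argument is a path to a JSON file of the same schema or a TSV with
    columns gene, side, nonamer, spacer, heptamer, coding_length_aa.
    """
    if path_or_default == "default":
        raw = resources.files("ighjkit.data").joinpath("germline.json").read_text()
        cfg = json.loads(raw)
    elif str(path_or_default).endswith(".tsv"):
        return _load_germline_tsv(str(path_or_default))
    else:
        with open(path_or_default) as fh:
            cfg = json.load(fh)

    ccfg = cfg.get("consensus", {})
    consensus = ConsensusSet(
        j_nonamer=ccfg.get("j_nonamer", "CCAAAAACA"),
        heptamer=ccfg.get("heptamer", "CACAGTG"),
        d_nonamer=ccfg.get("d_nonamer", "ACAAAAACC"),
    )
    genes: dict[str, GermlineGene] = {}
    for g in cfg.get("ighj", []):
        name = g.get("name", "<unnamed>")
        try:
            rss = reconstruct_rss(
                consensus,
                name,
                _mutations_from_config(g.get("nonamer_mutations", []), "nonamer", name)
                + _mutations_from_config(g.get("heptamer_mutations", []), "heptamer", name),
                spacer_length=int(g["spacer_length"]),
                side=Side.J_UPSTREAM,
                strict=False,
            )
        except KeyError as exc:
            raise ConfigError(f"{name}: missing field {exc}") from exc
        rss = replace(rss, discrepancies=rss.discrepancies + tuple(g.get("discrepancies", ())))
        aa = int(g["coding_length_aa"])
        genes[name] = GermlineGene(
            name=name,
            rss_set={Side.J_UPSTREAM: rss},
            coding_length_aa=aa,
            coding_seq=synthetic_coding_sequence(name, 3 * aa),
            metadata={
                "spacer_length_alternates": tuple(g.get("spacer_length_alternates", ())),
                "nonamer_mutation_keys": tuple(
                    MutationSpec("nonamer", int(m["position"]), m["frm"], m["to"]).key
                    for m in g.get("nonamer_mutations", [])
                ),
            },
        )
    for g in cfg.get("ighd", []):
        name = g.get("name", "<unnamed>")
        length_nt = int(g["coding_length_nt"])
        mk = lambda side: RSS(  # noqa: E731 - local shorthand
            gene_name=name,
            side=side,
            nonamer=consensus.d_nonamer,
            heptamer=consensus.heptamer,
            spacer_length=consensus.nominal_spacer_d,
        )
        genes[name] = GermlineGene(
            name=name,
            rss_set={Side.D_UPSTREAM: mk(Side.D_UPSTREAM), Side.D_DOWNSTREAM: mk(Side.D_DOWNSTREAM)},
            coding_length_aa=max(1, length_nt // 3),
            coding_seq=synthetic_coding_sequence(name, length_nt),
            metadata={"pairing_tier": g.get("pairing_tier", "medium")},
        )
    n_j = sum(1 for n in genes if n.startswith("IGHJ"))
    n_d = sum(1 for n in genes if n.startswith("IGHD"))
    if path_or_default == "default" and (n_j != 6 or n_d < 10):
        raise ConfigError(f"packaged germline incomplete: {n_j} IGHJ, {n_d} IGHD genes")
    return genes


def _load_germline_tsv(path: str) -> dict[str, GermlineGene]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"gene", "side", "nonamer", "spacer", "heptamer"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"germline TSV missing columns {sorted(missing)}")
    side_map = {s.value: s for s in Side}
    rss_by_gene: dict[str, dict[Side, RSS]] = {}
    aa_by_gene: dict[str, int] = {}
    for _, row in df.iterrows():
        gene = row["gene"]
        if row["side"] not in side_map:
            raise ConfigError(f"{gene}: unknown side {row['side']!r}")
        side = side_map[row["side"]]
        spacer = str(row["spacer"])
        if spacer.isdigit():
            slen, sseq = int(spacer), None
        else:
            slen, sseq = len(spacer), spacer
        rss_by_gene.setdefault(gene, {})[side] = RSS(
            gene_name=gene, side=side, nonamer=row["nonamer"], heptamer=row["heptamer"],
            spacer_length=slen, spacer=sseq,
        )
        if "coding_length_aa" in df.columns and not pd.isna(row["coding_length_aa"]):
            aa_by_gene[gene] = int(row["coding_length_aa"])
    genes = {}
    for gene, rset in rss_by_gene.items():
        aa = aa_by_gene.get(gene, 16)
        genes[gene] = GermlineGene(
            name=gene, rss_set=rset, coding_length_aa=aa,
            coding_seq=synthetic_coding_sequence(gene, 3 * aa),
        )
    return genes


def read_flanks_fasta(path: str) -> dict[str, str]:
    """Read raw germline flank sequences (FASTA) for RSS extraction."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
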