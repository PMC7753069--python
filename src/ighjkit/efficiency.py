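"""Mutation-specific relative joining frequencies and per-gene recombination weights.

Extrachromosomal-substrate experiments in pre-B cell lines measured how
single and double substitutions in the RSS nonamer and heptamer, and
changes in spacer length, alter the V(D)J joining frequency relative to
a consensus control (100%).  This module encodes those measured
percentages as a total lookup table and combines them, element by
element, into a relative recombination weight per germline gene:

    weight = (nonamer% / 100) x (heptamer% / 100) x (spacer% / 100)

Substitutions without a measured value fall back to a "moderate" default
(the measured moderate band for unlisted heptamer positions is
28.5-52.0%; the default sits inside it) and combine multiplicatively.

Two weight modes exist for gene choice in simulation:

* ``mechanistic`` - normalised products of element efficiencies; the
  hypothesis that usage tracks RSS quality, exploratory only.
* ``calibrated`` - a packaged vector chosen inside the observed usage
  bands (IGHJ4 > 40%, IGHJ6/3/5 10-20%, IGHJ2/1 < 4%); this is the mode
  asserted to reproduce the headline usage pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import DegenerateModelError, ParameterError
from .germline import ConsensusSet, GermlineGene, MutationSpec, RSS, Side, mismatch_profile

PROVENANCE_ORDER = {"literature_quoted": 0, "user_override": 1, "default_moderate": 2}

#: Artificial 12 bp spacer sequence with a measured joining frequency.
ARTIFICIAL_SPACER_12 = "GATCGATCGATC"


@dataclass(frozen=True)
class EfficiencyEntry:
    key: str  # e.g. "9-4G", "9-3G+9-4G", "len:13", "seq:GATCGATCGATC"
    value: float  # % of control, in [0, 100]
    provenance: str = "literature_quoted"
    bound: str | None = None  # "upper" encodes a printed "< value"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ParameterError(f"efficiency {self.key}={self.value} outside [0, 100]")
        if self.provenance not in PROVENANCE_ORDER:
            raise ParameterError(f"unknown provenance {self.provenance!r}")


@dataclass
class EfficiencyTable:
    """Total mapping from mutation keys to relative joining frequency (% of control)."""

    nonamer_entries: dict[str, EfficiencyEntry] = field(default_factory=dict)
    heptamer_entries: dict[str, EfficiencyEntry] = field(default_factory=dict)
    spacer12_entries: dict[str, EfficiencyEntry] = field(default_factory=dict)
    spacer23_entries: dict[str, EfficiencyEntry] = field(default_factory=dict)
    moderate_default: float = 40.0
    heptamer_moderate_band: tuple[float, float] = (28.5, 52.0)

    def _element_entries(self, element: str) -> dict[str, EfficiencyEntry]:
        return {"nonamer": self.nonamer_entries, "heptamer": self.heptamer_entries}[element]

    def lookup(self, element: str, key: str) -> EfficiencyEntry:
        """Total lookup: quoted entry if present, else the moderate default.

        Double keys ("9-3G+9-4G") are matched as a whole; an ``N``
        to-base in a stored double key is a wildcard for that position.
        """
        entries = self._element_entries(element)
        if key in entries:
            return entries[key]
        for stored, entry in entries.items():
            if "+" in stored and _double_key_matches(stored, key):
                return entry
        return EfficiencyEntry(key, self.moderate_default, provenance="default_moderate")

    def spacer_efficiency(
        self, spacer_length: int, nominal: int, spacer_seq: str | None = None
    ) -> EfficiencyEntry:
        entries = self.spacer12_entries if nominal == 12 else self.spacer23_entries
        if spacer_seq is not None and f"seq:{spacer_seq}" in entries:
            return entries[f"seq:{spacer_seq}"]
        key = f"len:{spacer_length}"
        if key in entries:
            return entries[key]
        # beyond the quoted/declared lengths: severe reduction
        return EfficiencyEntry(key, 1.0, provenance="default_moderate")


def _double_key_matches(stored: str, key: str) -> bool:
    sp = stored.split("+")
    kp = key.split("+")
    if len(sp) != len(kp):
        return False
    for s, k in zip(sorted(sp), sorted(kp)):
        if s.endswith("N"):
            s, k = s[:-1], k[:-1]
        if s != k:
            return False
    return True


def build_default_efficiency_table() -> EfficiencyTable:
    """The packaged table of measured relative joining frequencies.

    Values are percentages of the consensus control measured in cell-line
    recombination-substrate assays.  ``< 0.1%`` is stored as 0.1 with an
    upper-bound flag and used as a point value in products.  Spacer-23
    length penalties are declared defaults (one-nucleotide changes are
    only moderately deleterious, larger ones severe), not measured
    percentages, and are user-overridable.
    """
    q = EfficiencyEntry
    t = EfficiencyTable()
    t.nonamer_entries = {
        e.key: e
        for e in (
            q("wt", 100.0),
            q("9-2A", 2.7),
            q("9-2T", 12.9),
            q("9-2G", 61.3),
            q("9-4G", 27.3),
            q("9-5C", 10.4),
            q("9-3G+9-4G", 19.3),
            q("9-6G+9-7G", 26.0),
            q("9-8N+9-9A", 0.1, bound="upper"),
        )
    }
    t.heptamer_entries = {
        e.key: e
        for e in (
            q("wt", 100.0),
            q("7-1G", 0.0),
            q("7-2T", 0.5),
            q("7-3G", 0.6),
            q("7-5C", 5.9),
        )
    }
    t.spacer12_entries = {
        e.key: e
        for e in (
            q("len:12", 100.0),
            q("len:13", 11.0),
            q("len:11", 7.7),
            q("len:14", 0.0),
            q(f"seq:{ARTIFICIAL_SPACER_12}", 63.0),
        )
    }
    t.spacer23_entries = {
        e.key: e
        for e in (
            q("len:23", 100.0),
            q("len:22", 50.0, provenance="default_moderate"),
            q("len:24", 50.0, provenance="default_moderate"),
            q("len:21", 10.0, provenance="default_moderate"),
        )
    }
    return t


def _weakest(provenances: Sequence[str]) -> str:
    return max(provenances, key=lambda p: PROVENANCE_ORDER[p], default="literature_quoted")


def element_efficiency(
    mutations: Sequence[MutationSpec], element: str, table: EfficiencyTable
) -> tuple[float, str]:
    """Relative joining frequency (% of control) for one element's substitutions.

    An empty list is the control (100%).  A quoted single or double key
    returns its quoted value; otherwise each substitution contributes its
    own lookup and contributions combine multiplicatively.
    """
    muts = [m for m in mutations if m.element == element]
    if any(m.element not in (element,) for m in mutations):
        raise ParameterError("mutations must all belong to the requested element")
    if not muts:
        return 100.0, "literature_quoted"
    keys = sorted(m.key for m in muts)
    joint = "+".join(keys)
    entries = table._element_entries(element)
    if joint in entries:
        e = entries[joint]
        return e.value, e.provenance
    if len(keys) > 1:
        for stored, e in entries.items():
            if "+" in stored and _double_key_matches(stored, joint):
                return e.value, e.provenance
    value = 100.0
    provs = []
    for k in keys:
        e = table.lookup(element, k)
        value *= e.value / 100.0
        provs.append(e.provenance)
    return value, _weakest(provs)


def rss_efficiency(
    rss: RSS, consensus: ConsensusSet | None = None, table: EfficiencyTable | None = None
) -> float:
    """Relative recombination weight of one RSS in [0, 1].

    Product of nonamer, heptamer and spacer efficiencies; monotone
    non-increasing under added mutations when all table entries are
    <= 100%.
    """
    consensus = consensus or ConsensusSet()
    table = table or build_default_efficiency_table()
    profile = mismatch_profile(rss, consensus)
    non_pct, _ = element_efficiency(
        [m for m in profile if m.element == "nonamer"], "nonamer", table
    )
    hep_pct, _ = element_efficiency(
        [m for m in profile if m.element == "heptamer"], "heptamer", table
    )
    spc = table.spacer_efficiency(
        rss.spacer_length, rss.nominal_spacer_length, spacer_seq=rss.spacer
    )
    return (non_pct / 100.0) * (hep_pct / 100.0) * (spc.value / 100.0)


#: Gene-choice vector chosen inside the observed usage bands; a
#: calibration, not a measurement (the field reports bands, not a vector).
CALIBRATED_J_WEIGHTS: dict[str, float] = {
    "IGHJ1": 0.02,
    "IGHJ2": 0.03,
    "IGHJ3": 0.16,
    "IGHJ4": 0.47,
    "IGHJ5": 0.14,
    "IGHJ6": 0.18,
}

#: Default relative D-gene weights by observed pairing tier.
D_TIER_WEIGHTS = {"high": 9.0, "medium": 3.0, "low": 1.0}


@dataclass(frozen=True)
class GeneWeights:
    weights: Mapping[str, float]
    mode: str  # "mechanistic" | "calibrated"
    normalized: bool = True

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ParameterError("gene weights must be non-negative")
        if self.normalized:
            total = sum(self.weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(f"normalized weights sum to {total}, not 1")

    def __getitem__(self, gene: str) -> float:
        return self.weights[gene]


def gene_weights(
    germline: Mapping[str, GermlineGene],
    table: EfficiencyTable | None = None,
    mode: str = "calibrated",
    consensus: ConsensusSet | None = None,
) -> GeneWeights:
    """Normalised gene-choice probabilities for the J (or D) genes given.

    ``mechanistic`` derives each gene's weight from its RSS via
    :func:`rss_efficiency`; ``calibrated`` uses the packaged band-level
    vector (IGHJ genes) or pairing-tier weights (IGHD genes).
    """
    if not germline:
        raise ParameterError("germline set is empty")
    raw: dict[str, float] = {}
    for name, gene in germline.items():
        if mode == "mechanistic":
            raw[name] = rss_efficiency(gene.primary_rss, consensus, table)
        elif mode == "calibrated":
            if name in CALIBRATED_J_WEIGHTS:
                raw[name] = CALIBRATED_J_WEIGHTS[name]
            elif name.startswith("IGHD"):
                tier = str(gene.metadata.get("pairing_tier", "medium"))
                raw[name] = D_TIER_WEIGHTS.get(tier, D_TIER_WEIGHTS["medium"])
            else:
                raise ParameterError(f"no calibrated weight defined for {name}")
        else:
            raise ParameterError(f"unknown weight mode {mode!r}")
    total = sum(raw.values())
    if total <= 0:
        raise DegenerateModelError("all gene weights are zero; cannot normalise")
    return GeneWeights({k: v / total for k, v in raw.items()}, mode=mode)
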