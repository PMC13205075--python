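"""Domain types shared across the pipeline.

The central container is :class:`ExpressionMatrix`, a validated wrapper
around a features × samples integer count table with per-feature RNA-class
labels and per-sample group labels. The remaining types are lightweight
records (dataclasses) passed between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA", "circRNA")
GROUPS = ("cold", "control")
#: classes whose features carry a nucleotide sequence in this pipeline
SEQUENCE_CLASSES = ("mRNA", "lncRNA", "miRNA", "circRNA")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
#: canonical strength ranking, strongest first
SITE_TYPE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

NAMESPACES = ("BP", "MF", "CC", "pathway")


@dataclass
class ExpressionMatrix:
    """Raw integer counts for features of four RNA classes across grouped samples.

    Parameters
    ----------
    counts
        DataFrame of shape (features, samples); index = feature ids,
        columns = sample ids, values non-negative integers.
    rna_class
        Mapping feature id -> class label in :data:`RNA_CLASSES`.
    group
        Mapping sample id -> group label in :data:`GROUPS`.
    """

    counts: pd.DataFrame
    rna_class: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dup[:5]}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup[:5]}")
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            # allow float input only if exactly integral and finite
            if not np.all(np.isfinite(values)):
                raise FormatError("counts contain non-finite values")
            if not np.all(values == np.floor(values)):
                bad = np.argwhere(values != np.floor(values))[0]
                raise FormatError(
                    f"non-integer count at feature {c.index[bad[0]]!r}, "
                    f"sample {c.columns[bad[1]]!r}"
                )
            c = c.astype(np.int64)
            self.counts = c
            values = c.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at feature {c.index[bad[0]]!r}, "
                f"sample {c.columns[bad[1]]!r}"
            )
        self.rna_class = pd.Series(self.rna_class).reindex(c.index)
        if self.rna_class.isna().any():
            missing = self.rna_class.index[self.rna_class.isna()].tolist()
            raise FormatError(f"features missing an RNA class: {missing[:5]}")
        bad_cls = set(self.rna_class.unique()) - set(RNA_CLASSES)
        if bad_cls:
            raise FormatError(f"unknown RNA classes: {sorted(bad_cls)}")
        self.group = pd.Series(self.group).reindex(c.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()].tolist()
            raise FormatError(f"samples missing a group: {missing[:5]}")
        bad_grp = set(self.group.unique()) - set(GROUPS)
        if bad_grp:
            raise FormatError(f"unknown groups: {sorted(bad_grp)}")

    @property
    def feature_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    def samples_in_group(self, group: str) -> list[str]:
        return self.group.index[self.group == group].tolist()

    def features_in_class(self, rna_class: str) -> list[str]:
        return self.rna_class.index[self.rna_class == rna_class].tolist()

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts.loc[list(feature_ids)],
            rna_class=self.rna_class.loc[list(feature_ids)],
            group=self.group,
        )


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic location and class of one feature (0-based, half-open)."""

    feature_id: str
    rna_class: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise FormatError(f"unknown RNA class {self.rna_class!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"{self.feature_id}: coordinates must satisfy 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.feature_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class TermAnnotation:
    """One functional term (GO category or pathway) with its member features."""

    term_id: str
    term_name: str
    namespace: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise FormatError(f"unknown namespace {self.namespace!r}")
        if not self.members:
            raise FormatError(f"term {self.term_id!r} has no members")


@dataclass
class DERecord:
    """Per-feature differential-expression result.

    ``log10_fc`` is the base-10 log of (cold + pseudocount)/(control +
    pseudocount) on group means of normalized counts. ``status`` is filled by
    class-specific volcano classification (up / down / ns).
    """

    feature_id: str
    rna_class: str
    base_mean: float
    log10_fc: float
    se_log: float
    p: float
    p_adj: float | None = None
    status: str | None = None


@dataclass(frozen=True)
class SeedSite:
    """One canonical seed-match occurrence on a target sequence.

    ``position`` is the 0-based start of the full matched site on the target
    (so 7mer-m8 and 8mer sites start one nucleotide 5' of the 6-mer core).
    """

    mirna_id: str
    target_id: str
    position: int
    site_type: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise FormatError(f"unknown site type {self.site_type!r}")

    @property
    def length(self) -> int:
        return {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[self.site_type]


@dataclass(frozen=True)
class Interaction:
    """A miRNA -> target relation supported by >= 1 seed site."""

    mirna_id: str
    target_id: str
    target_class: str
    n_sites: int
    best_site_type: str


@dataclass(frozen=True)
class LncTargetPair:
    """A lncRNA -> mRNA relation via genomic proximity (cis) or correlation (trans).

    ``evidence`` is the gap distance in bp for cis pairs and the Pearson r for
    trans pairs.
    """

    lnc_id: str
    mrna_id: str
    mode: str
    evidence: float


@dataclass(frozen=True)
class CeRNATriad:
    """An (mRNA, miRNA, sponge) triple passing the direction-consistency rules.

    The mRNA and miRNA must move in opposite directions; the sponge (lncRNA
    or circRNA) must move with the mRNA; the miRNA must have predicted seed
    sites in both the mRNA and the sponge.
    """

    mrna_id: str
    mirna_id: str
    sponge_id: str
    sponge_class: str
    mrna_status: str
    mirna_status: str
    sponge_status: str
    mirna_targets_mrna: bool = True
    sponge_binds_mirna: bool = True
    lnc_mode: str = "n/a"

    def __post_init__(self) -> None:
        if self.sponge_class not in ("lncRNA", "circRNA"):
            raise FormatError(f"sponge class must be lncRNA or circRNA, got {self.sponge_class!r}")
        for s in (self.mrna_status, self.mirna_status, self.sponge_status):
            if s not in ("up", "down"):
                raise FormatError(f"triad member status must be up/down, got {s!r}")
        if self.mrna_status == self.mirna_status:
            raise FormatError("mRNA and miRNA directions must be opposite")
        if self.sponge_status != self.mrna_status:
            raise FormatError("sponge and mRNA directions must match")
        if not (self.mirna_targets_mrna and self.sponge_binds_mirna):
            raise FormatError("both targeting evidences must hold")
        if self.lnc_mode not in ("cis", "trans", "n/a"):
            raise FormatError(f"unknown lnc mode {self.lnc_mode!r}")


@dataclass(frozen=True)
class EnrichmentRecord:
    """Over-representation result for one term.

    N = universe size, K = term size in universe, n = selected-set size in
    universe, k = overlap; gene_ratio = k/n is the reporting/ranking key.
    """

    term_id: str
    namespace: str
    k: int
    n: int
    K: int
    N: int
    gene_ratio: float
    p: float
    p_adj: float | None = None


@dataclass
class SimulationConfig:
    """Parameters of one synthetic two-group experiment.

    Defaults emulate the study design this pipeline targets: two groups of
    three biological replicates, negative-binomial counts with dispersion
    0.1 (variance = mu + alpha * mu^2), baseline means log-uniform over
    10^0.5 .. 10^3.5, planted effects of |log10 FC| = 1.0.
    """

    n_mrna: int = 2000
    n_lncrna: int = 300
    n_mirna: int = 150
    n_circrna: int = 500
    n_per_group: int = 3
    baseline_mean_log10_range: tuple[float, float] = (0.5, 3.5)
    dispersion: float = 0.1
    n_de_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"mRNA": 60, "lncRNA": 24, "miRNA": 24, "circRNA": 30}
    )
    planted_log10fc: float = 1.0
    n_triads: int = 20
    mrna_seq_len: int = 500
    lncrna_seq_len: int = 500
    circrna_seq_len: int = 500
    mirna_seq_len: int = 22
    n_terms: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = {
            "mRNA": self.n_mrna,
            "lncRNA": self.n_lncrna,
            "miRNA": self.n_mirna,
            "circRNA": self.n_circrna,
        }
        for cls, n_de in dict(self.n_de_per_class).items():
            if n_de > sizes[cls]:
                raise FormatError(
                    f"n_de_per_class[{cls}] = {n_de} exceeds class size {sizes[cls]}"
                )
        if self.planted_log10fc < 0:
            raise FormatError("planted_log10fc must be >= 0")
        if self.dispersion <= 0:
            raise FormatError("dispersion must be > 0")
        if self.n_per_group < 1:
            raise FormatError("n_per_group must be >= 1")
        if self.seed is None:
            raise FormatError("seed is mandatory")
        lo, hi = self.baseline_mean_log10_range
        if not lo < hi:
            raise FormatError("baseline_mean_log10_range must be an increasing pair")
        # lncRNA sponges appear in half the triads (alternating pattern);
        # each class must be able to host its triad members
        n_lnc_triads = self.n_triads // 2
        n_circ_triads = self.n_triads - n_lnc_triads
        need = {
            "mRNA": self.n_triads,
            "miRNA": self.n_triads,
            "lncRNA": n_lnc_triads,
            "circRNA": n_circ_triads,
        }
        for cls, k in need.items():
            if k > dict(self.n_de_per_class).get(cls, 0):
                raise FormatError(
                    f"{cls}: {k} triad members exceed n_de_per_class[{cls}]"
                )


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`cernascreen.synthetic.simulate_experiment`."""

    #: feature id -> ("up"|"down"|"ns", signed planted log10 FC)
    de_status: dict[str, tuple[str, float]]
    #: (mirna_id, target_id, position, site_type) planted in target sequences
    planted_sites: list[tuple[str, str, int, str]]
    planted_triads: list[CeRNATriad]
    #: the two adipocyte-marker feature ids carrying planted group effects
    marker_ids: tuple[str, str]
    #: the marker-normalized focal gene (planted down, e.g. an ADIPOQ analogue)
    normalization_target: str | None = None
    #: term id of the planted enriched term ("lipid storage" analogue)
    enriched_term_id: str | None = None
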