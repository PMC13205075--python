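"""ceRNA triad assembly, Venn-style overlap reporting, marker normalization.

A ceRNA (competing endogenous RNA) triad is (mRNA, miRNA, sponge) where
the sponge is a lncRNA or circRNA that shares the miRNA's binding sites
with the mRNA. The direction-consistency rules are the screen's core:

* mRNA and miRNA must move in opposite directions across the two groups;
* the sponge must move with the mRNA;
* the miRNA must have predicted seed sites in both the mRNA and the sponge;
* a lncRNA sponge must additionally be a cis or trans target-relation
  partner of the core mRNA (circRNA sponges need only the seed sites).

``marker_normalize`` rescales a focal gene's expression by adipocyte
marker genes to separate transcriptional regulation from changing cell
composition: with geometric form, x_target / sqrt(x_markA * x_markB) per
sample (a plain-product denominator is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import normalized_counts
from .errors import ConsistencyError, FormatError
from .types import (
    CeRNATriad,
    DERecord,
    ExpressionMatrix,
    Interaction,
    LncTargetPair,
    RNA_CLASSES,
)


@dataclass
class VennReport:
    """Per-class differential sets and their pairwise targeting overlaps."""

    de_by_class: dict[str, set[str]]
    #: (class_a, class_b) -> (set of class_a ids in >=1 relation with a DE
    #: class_b feature, same for class_b side)
    overlaps: dict[tuple[str, str], tuple[set[str], set[str]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in RNA_CLASSES:
            rows.append(("de", cls, "", len(self.de_by_class.get(cls, set()))))
        for (a, b), (sa, sb) in sorted(self.overlaps.items()):
            rows.append(("overlap", a, b, len(sa)))
            rows.append(("overlap", b, a, len(sb)))
        return pd.DataFrame(rows, columns=["kind", "class_a", "class_b", "count"])


def venn_overlap(
    de_records: Sequence[DERecord],
    interactions: Sequence[Interaction],
    lnc_pairs: Sequence[LncTargetPair],
) -> VennReport:
    """Count DE features participating in targeting relations with DE partners.

    Produces per-class DE sets and, for each related class pair
    (miRNA vs mRNA/lncRNA/circRNA from seed-site interactions; lncRNA vs
    mRNA from cis/trans pairs), the subset of DE features on each side that
    have at least one relation to a DE feature on the other side.
    """
    de = {r.feature_id: r for r in de_records if r.status in ("up", "down")}
    de_by_class: dict[str, set[str]] = {c: set() for c in RNA_CLASSES}
    for fid, r in de.items():
        de_by_class[r.rna_class].add(fid)
    overlaps: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    for target_class in ("mRNA", "lncRNA", "circRNA"):
        mi_side: set[str] = set()
        tg_side: set[str] = set()
        for it in interactions:
            if it.target_class != target_class:
                continue
            if it.mirna_id in de and it.target_id in de:
                mi_side.add(it.mirna_id)
                tg_side.add(it.target_id)
        overlaps[("miRNA", target_class)] = (mi_side, tg_side)
    lnc_side: set[str] = set()
    m_side: set[str] = set()
    for p in lnc_pairs:
        if p.lnc_id in de and p.mrna_id in de:
            lnc_side.add(p.lnc_id)
            m_side.add(p.mrna_id)
    overlaps[("lncRNA", "mRNA")] = (lnc_side, m_side)
    return VennReport(de_by_class=de_by_class, overlaps=overlaps)


def assemble_triads(
    de_records: Sequence[DERecord],
    interactions: Sequence[Interaction],
    lnc_pairs: Sequence[LncTargetPair],
    keep_mrna_ids: set[str] | None = None,
) -> list[CeRNATriad]:
    """Enumerate direction-consistent (mRNA, miRNA, sponge) triads.

    For every differential mRNA m, every differential miRNA with the
    opposite direction and a seed-site interaction with m, and every
    differential sponge with m's direction and a seed-site interaction
    with the same miRNA (lncRNA sponges additionally requiring a cis or
    trans relation with m), one triad is emitted. Output is de-duplicated
    and sorted by (mrna_id, mirna_id, sponge_id).

    ``keep_mrna_ids`` is an optional post-filter restricting triads to core
    mRNAs in a term set of interest (e.g. a lipid-storage annotation).
    """
    status = {r.feature_id: r.status for r in de_records if r.status in ("up", "down")}
    cls = {r.feature_id: r.rna_class for r in de_records}
    # index seed-site interactions among DE features by miRNA
    mirna_to_mrnas: dict[str, set[str]] = {}
    mirna_to_sponges: dict[str, set[str]] = {}
    for it in interactions:
        if it.mirna_id not in status or it.target_id not in status:
            continue
        if it.target_class == "mRNA":
            mirna_to_mrnas.setdefault(it.mirna_id, set()).add(it.target_id)
        elif it.target_class in ("lncRNA", "circRNA"):
            mirna_to_sponges.setdefault(it.mirna_id, set()).add(it.target_id)
    lnc_partner_mode: dict[tuple[str, str], str] = {}
    for p in lnc_pairs:
        key = (p.lnc_id, p.mrna_id)
        # cis evidence takes precedence when both modes hold
        if key not in lnc_partner_mode or p.mode == "cis":
            lnc_partner_mode[key] = p.mode
    triads: set[CeRNATriad] = set()
    for mirna_id, mrnas in mirna_to_mrnas.items():
        sponges = mirna_to_sponges.get(mirna_id, set())
        if not sponges:
            continue
        for m in mrnas:
            if status[m] == status[mirna_id]:
                continue  # mRNA and miRNA must be opposite
            if keep_mrna_ids is not None and m not in keep_mrna_ids:
                continue
            for s in sponges:
                if status[s] != status[m]:
                    continue  # sponge must move with the mRNA
                sponge_class = cls[s]
                if sponge_class == "lncRNA":
                    mode = lnc_partner_mode.get((s, m))
                    if mode is None:
                        continue
                else:
                    mode = "n/a"
                triads.add(
                    CeRNATriad(
                        mrna_id=m,
                        mirna_id=mirna_id,
                        sponge_id=s,
                        sponge_class=sponge_class,
                        mrna_status=status[m],
                        mirna_status=status[mirna_id],
                        sponge_status=status[s],
                        lnc_mode=mode,
                    )
                )
    return sorted(triads, key=lambda t: (t.mrna_id, t.mirna_id, t.sponge_id))


def marker_normalize(
    matrix: ExpressionMatrix,
    factors: pd.Series,
    target_id: str,
    marker_a_id: str,
    marker_b_id: str,
    form: str = "geometric",
) -> pd.DataFrame:
    """Per-sample marker-normalized expression of a focal gene.

    geometric (default): x_target / sqrt(x_markA * x_markB);
    product: x_target / (x_markA * x_markB). All on normalized counts.
    Returns a DataFrame with columns sample_id, group, value. Raises when a
    marker has zero normalized expression in any sample (naming the sample).
    """
    if form not in ("geometric", "product"):
        raise FormatError(f"unknown normalization form {form!r}")
    norm = normalized_counts(matrix, factors)
    for fid in (target_id, marker_a_id, marker_b_id):
        if fid not in norm.index:
            raise ConsistencyError(f"feature {fid!r} absent from the matrix")
    x = norm.loc[target_id]
    a = norm.loc[marker_a_id]
    b = norm.loc[marker_b_id]
    for marker_id, values in ((marker_a_id, a), (marker_b_id, b)):
        zero = values.index[values <= 0].tolist()
        if zero:
            raise FormatError(
                f"marker {marker_id!r} has zero expression in sample(s) {zero}"
            )
    denom = np.sqrt(a * b) if form == "geometric" else a * b
    values = x / denom
    return pd.DataFrame(
        {
            "sample_id": norm.columns,
            "group": matrix.group.loc[norm.columns].values,
            "value": values.values,
        }
    )


def group_ttest(values: Sequence[float], groups: Sequence[str]) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t-test (two-sided).

    Degenerate inputs: zero pooled variance with equal means gives
    (t=0, p=1); zero pooled variance with unequal means is an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ConsistencyError(f"need exactly 2 groups, got {list(labels)}")
    x = values[groups == labels[0]]
    y = values[groups == labels[1]]
    if len(x) < 2 or len(y) < 2:
        raise ConsistencyError("need >= 2 values per group")
    pooled_var = (np.var(x, ddof=1) * (len(x) - 1) + np.var(y, ddof=1) * (len(y) - 1)) / (
        len(x) + len(y) - 2
    )
    if pooled_var == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise FormatError("zero pooled variance with unequal means: t undefined")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def sign_concordance(
    lfc_seq: Mapping[str, float],
    lfc_qpcr: Mapping[str, float],
) -> float:
    """Fraction of shared features whose fold-change signs agree.

    A zero fold change is discordant with any nonzero one (and concordant
    with another zero). Raises on an empty intersection.
    """
    shared = sorted(set(lfc_seq) & set(lfc_qpcr))
    if not shared:
        raise ConsistencyError("no shared features between the two fold-change maps")
    agree = sum(1 for f in shared if np.sign(lfc_seq[f]) == np.sign(lfc_qpcr[f]))
    return agree / len(shared)


def triad_table(triads: Sequence[CeRNATriad]) -> pd.DataFrame:
    """Tabulate triads (one row each) for TSV export."""
    return pd.DataFrame(
        {
            "mrna_id": [t.mrna_id for t in triads],
            "mirna_id": [t.mirna_id for t in triads],
            "sponge_id": [t.sponge_id for t in triads],
            "sponge_class": [t.sponge_class for t in triads],
            "mrna_status": [t.mrna_status for t in triads],
            "mirna_status": [t.mirna_status for t in triads],
            "sponge_status": [t.sponge_status for t in triads],
            "lnc_mode": [t.lnc_mode for t in triads],
        }
    )
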