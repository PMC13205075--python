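"""miRNA seed-site prediction and lncRNA-mRNA target relations.

Seed sites follow the canonical site taxonomy. Writing the miRNA 5'->3',
its seed is positions 2-7; a target site (written 5'->3' on the target) is
an occurrence of the reverse complement of that 6-mer ("core"). The four
canonical classes, strongest first:

======== ==========================================================
8mer     core preceded by the complement of miRNA position 8 and
         followed by an A on the target
7mer-m8  core preceded by the complement of miRNA position 8
7mer-A1  core followed by an A on the target
6mer     the bare core
======== ==========================================================

Each core occurrence is reported once with its highest-ranking class;
overlapping occurrences are independent sites. circRNA targets are scanned
as linear strings by default; ``circular=True`` extends the scan across
the back-splice junction by appending the first (site length - 1)
nucleotides.

lncRNA-mRNA relations come in two modes: cis (same chromosome within a
genomic window, default 100 kb) and trans (absolute Pearson correlation of
log10 normalized expression above a threshold, default 0.9).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError
from .types import (
    ExpressionMatrix,
    FeatureAnnotation,
    Interaction,
    LncTargetPair,
    SeedSite,
    SITE_TYPE_RANK,
)
from .diffexpr import normalized_counts

DEFAULT_CIS_WINDOW = 100_000
DEFAULT_TRANS_R = 0.9

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (ACGU alphabet)."""
    _check_rna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _check_rna(seq: str) -> None:
    bad = set(seq) - set("ACGUN")
    if bad:
        raise FormatError(f"non-RNA characters {sorted(bad)} in sequence")


def seed_sites(
    mirna_id: str,
    mirna_seq: str,
    target_id: str,
    target_seq: str,
    circular: bool = False,
) -> list[SeedSite]:
    """All canonical seed-site occurrences of one miRNA on one target.

    Returns sites sorted by position; each core occurrence appears once
    with its highest-ranking type. Site positions are the 0-based start of
    the full matched site on the (linear) target.
    """
    _check_rna(mirna_seq)
    _check_rna(target_seq)
    if len(mirna_seq) < 8:
        raise FormatError(f"{mirna_id}: miRNA must be >= 8 nt for seed classification")
    core = reverse_complement(mirna_seq[1:7])  # pairs miRNA positions 2-7
    m8_match = reverse_complement(mirna_seq[7])  # complement of miRNA position 8
    scan_seq = target_seq
    if circular and len(target_seq) >= 8:
        scan_seq = target_seq + target_seq[:7]  # longest site is 8 nt
    linear_len = len(target_seq)
    sites: list[SeedSite] = []
    start = 0
    while True:
        p = scan_seq.find(core, start)
        if p == -1 or p >= linear_len:
            break
        start = p + 1
        if p >= 1:
            has_m8 = scan_seq[p - 1] == m8_match
        else:
            # only reachable with circular=True where the junction wraps
            has_m8 = circular and target_seq[-1] == m8_match
        has_a1 = p + 6 < len(scan_seq) and scan_seq[p + 6] == "A"
        if has_m8 and has_a1:
            site_type, pos = "8mer", p - 1
        elif has_m8:
            site_type, pos = "7mer-m8", p - 1
        elif has_a1:
            site_type, pos = "7mer-A1", p
        else:
            site_type, pos = "6mer", p
        # on a linear target every site extent fits within the sequence by
        # construction; on a circular one a junction site may wrap (pos is
        # still the linear 0-based start, pos = -1 meaning the last base)
        sites.append(
            SeedSite(mirna_id=mirna_id, target_id=target_id, position=pos, site_type=site_type)
        )
    return sites


def build_interactions(
    mirna_seqs: Mapping[str, str],
    target_seqs: Mapping[str, str],
    target_classes: Mapping[str, str],
    circular_classes: Sequence[str] = (),
    min_site_type: str = "6mer",
) -> list[Interaction]:
    """Aggregate seed sites over all (miRNA, target) pairs into interactions.

    Only pairs with >= 1 qualifying site materialize. Output is sorted by
    (mirna_id, target_id). ``circular_classes`` lists target classes scanned
    across the back-splice junction (typically ("circRNA",) when enabled).
    ``min_site_type`` sets the weakest site class that counts as evidence
    ("6mer" keeps everything; "7mer-A1" is the usual screening bar, since
    bare 6mers are weak and frequent by chance).
    """
    if not mirna_seqs or not target_seqs:
        raise FormatError("sequence maps must be non-empty")
    if min_site_type not in SITE_TYPE_RANK:
        raise FormatError(f"unknown site type {min_site_type!r}")
    max_rank = SITE_TYPE_RANK[min_site_type]
    missing = [t for t in target_seqs if t not in target_classes]
    if missing:
        raise ConsistencyError(f"targets lacking an RNA class: {missing[:5]}")
    interactions: list[Interaction] = []
    for mirna_id in sorted(mirna_seqs):
        for target_id in sorted(target_seqs):
            circular = target_classes[target_id] in circular_classes
            sites = seed_sites(
                mirna_id, mirna_seqs[mirna_id], target_id, target_seqs[target_id],
                circular=circular,
            )
            sites = [s for s in sites if SITE_TYPE_RANK[s.site_type] <= max_rank]
            if not sites:
                continue
            best = min(sites, key=lambda s: SITE_TYPE_RANK[s.site_type])
            interactions.append(
                Interaction(
                    mirna_id=mirna_id,
                    target_id=target_id,
                    target_class=target_classes[target_id],
                    n_sites=len(sites),
                    best_site_type=best.site_type,
                )
            )
    return interactions


def lnc_cis_targets(
    lnc_annotations: Sequence[FeatureAnnotation],
    mrna_annotations: Sequence[FeatureAnnotation],
    window: int = DEFAULT_CIS_WINDOW,
) -> list[LncTargetPair]:
    """lncRNA-mRNA pairs on the same chromosome within ``window`` bp.

    The evidence is the gap distance (0 for overlapping intervals).
    """
    for a in list(lnc_annotations) + list(mrna_annotations):
        if not isinstance(a, FeatureAnnotation):
            raise FormatError(f"annotation required, got {type(a).__name__}")
    pairs: list[LncTargetPair] = []
    by_chrom: dict[str, list[FeatureAnnotation]] = {}
    for m in mrna_annotations:
        by_chrom.setdefault(m.chrom, []).append(m)
    for l in sorted(lnc_annotations, key=lambda a: a.feature_id):
        for m in sorted(by_chrom.get(l.chrom, []), key=lambda a: a.feature_id):
            gap = max(l.start, m.start) - min(l.end, m.end)
            distance = max(gap, 0)
            if distance <= window:
                pairs.append(
                    LncTargetPair(lnc_id=l.feature_id, mrna_id=m.feature_id, mode="cis", evidence=float(distance))
                )
    return pairs


def lnc_trans_targets(
    matrix: ExpressionMatrix,
    factors: pd.Series,
    lnc_ids: Sequence[str],
    mrna_ids: Sequence[str],
    r_threshold: float = DEFAULT_TRANS_R,
) -> list[LncTargetPair]:
    """lncRNA-mRNA pairs with |Pearson r| >= threshold on log10(normalized + 1).

    Correlations are computed across all samples; zero-variance features are
    excluded with a warning (not an error). Needs >= 4 samples.
    """
    if matrix.counts.shape[1] < 4:
        raise ConsistencyError("trans correlation needs >= 4 samples")
    log_norm = np.log10(normalized_counts(matrix, factors) + 1.0)

    def _usable(ids: Sequence[str]) -> list[str]:
        keep = []
        for fid in ids:
            if log_norm.loc[fid].std(ddof=1) == 0:
                warnings.warn(f"zero-variance feature {fid!r} excluded from trans targeting")
            else:
                keep.append(fid)
        return keep

    lnc_use, mrna_use = _usable(lnc_ids), _usable(mrna_ids)
    pairs: list[LncTargetPair] = []
    if not lnc_use or not mrna_use:
        return pairs
    lmat = log_norm.loc[lnc_use].to_numpy()
    mmat = log_norm.loc[mrna_use].to_numpy()
    lz = (lmat - lmat.mean(axis=1, keepdims=True)) / lmat.std(axis=1, ddof=1, keepdims=True)
    mz = (mmat - mmat.mean(axis=1, keepdims=True)) / mmat.std(axis=1, ddof=1, keepdims=True)
    r = lz @ mz.T / (lmat.shape[1] - 1)
    for i, l in enumerate(lnc_use):
        for j, m in enumerate(mrna_use):
            if abs(r[i, j]) >= r_threshold:
                pairs.append(LncTargetPair(lnc_id=l, mrna_id=m, mode="trans", evidence=float(r[i, j])))
    return sorted(pairs, key=lambda p: (p.lnc_id, p.mrna_id))
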