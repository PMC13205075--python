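"""Triad assembly vs brute force, overlap report, marker normalization, t-test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cernascreen import cerna
from cernascreen.errors import ConsistencyError, FormatError
from cernascreen.types import (
    CeRNATriad,
    DERecord,
    ExpressionMatrix,
    Interaction,
    LncTargetPair,
)


def _rec(fid, cls, status, lfc=1.0):
    p = 1e-6 if status in ("up", "down") else 0.5
    return DERecord(feature_id=fid, rna_class=cls, base_mean=10.0,
                    log10_fc=lfc if status != "down" else -lfc,
                    se_log=0.1, p=p, status=status)


def _inter(mirna, target, cls):
    return Interaction(mirna_id=mirna, target_id=target, target_class=cls,
                       n_sites=1, best_site_type="8mer")


# ---------------------------------------------------------------------------
# triad assembly


def test_single_circ_triad_assembled():
    records = [_rec("m1", "mRNA", "up"), _rec("mi1", "miRNA", "down"),
               _rec("c1", "circRNA", "up")]
    interactions = [_inter("mi1", "m1", "mRNA"), _inter("mi1", "c1", "circRNA")]
    [t] = cerna.assemble_triads(records, interactions, [])
    assert (t.mrna_id, t.mirna_id, t.sponge_id) == ("m1", "mi1", "c1")
    assert t.lnc_mode == "n/a"


def test_same_direction_mirna_blocks_triad():
    records = [_rec("m1", "mRNA", "up"), _rec("mi1", "miRNA", "up"),
               _rec("c1", "circRNA", "up")]
    interactions = [_inter("mi1", "m1", "mRNA"), _inter("mi1", "c1", "circRNA")]
    assert cerna.assemble_triads(records, interactions, []) == []


def test_sponge_direction_must_match_mrna():
    records = [_rec("m1", "mRNA", "up"), _rec("mi1", "miRNA", "down"),
               _rec("c1", "circRNA", "down")]
    interactions = [_inter("mi1", "m1", "mRNA"), _inter("mi1", "c1", "circRNA")]
    assert cerna.assemble_triads(records, interactions, []) == []


def test_lncrna_sponge_requires_partner_relation():
    records = [_rec("m1", "mRNA", "down"), _rec("mi1", "miRNA", "up"),
               _rec("l1", "lncRNA", "down")]
    interactions = [_inter("mi1", "m1", "mRNA"), _inter("mi1", "l1", "lncRNA")]
    assert cerna.assemble_triads(records, interactions, []) == []
    pairs = [LncTargetPair(lnc_id="l1", mrna_id="m1", mode="trans", evidence=0.95)]
    [t] = cerna.assemble_triads(records, interactions, pairs)
    assert t.lnc_mode == "trans"


def test_ns_members_never_appear():
    records = [_rec("m1", "mRNA", "ns"), _rec("mi1", "miRNA", "down"),
               _rec("c1", "circRNA", "up")]
    interactions = [_inter("mi1", "m1", "mRNA"), _inter("mi1", "c1", "circRNA")]
    assert cerna.assemble_triads(records, interactions, []) == []


def _brute_force_triads(records, interactions, lnc_pairs):
    """Literal cubic enumeration of all (mRNA, miRNA, sponge) triples."""
    status = {r.feature_id: r.status for r in records}
    cls = {r.feature_id: r.rna_class for r in records}
    has = {(i.mirna_id, i.target_id) for i in interactions}
    partners = {(p.lnc_id, p.mrna_id) for p in lnc_pairs}
    de = [r.feature_id for r in records if r.status in ("up", "down")]
    out = set()
    for m, mu, s in itertools.product(de, repeat=3):
        if cls[m] != "mRNA" or cls[mu] != "miRNA" or cls[s] not in ("lncRNA", "circRNA"):
            continue
        if status[m] == status[mu] or status[s] != status[m]:
            continue
        if (mu, m) not in has or (mu, s) not in has:
            continue
        if cls[s] == "lncRNA" and (s, m) not in partners:
            continue
        out.add((m, mu, s))
    return out


def _random_instance(rng, n_per_class=8):
    records, interactions, lnc_pairs = [], [], []
    classes = {"m": "mRNA", "i": "miRNA", "l": "lncRNA", "c": "circRNA"}
    for prefix, cls in classes.items():
        for k in range(n_per_class):
            status = rng.choice(["up", "down", "ns"])
            records.append(_rec(f"{prefix}{k}", cls, status))
    for mu in range(n_per_class):
        for t in range(n_per_class):
            for prefix, cls in (("m", "mRNA"), ("l", "lncRNA"), ("c", "circRNA")):
                if rng.random() < 0.3:
                    interactions.append(_inter(f"i{mu}", f"{prefix}{t}", cls))
    for l in range(n_per_class):
        for m in range(n_per_class):
            if rng.random() < 0.3:
                lnc_pairs.append(LncTargetPair(
                    lnc_id=f"l{l}", mrna_id=f"m{m}",
                    mode=rng.choice(["cis", "trans"]), evidence=1.0))
    return records, interactions, lnc_pairs


def test_assembly_equals_cubic_brute_force_on_random_instances():
    rng = np.random.default_rng(17)
    for _ in range(25):
        records, interactions, lnc_pairs = _random_instance(rng)
        got = {(t.mrna_id, t.mirna_id, t.sponge_id)
               for t in cerna.assemble_triads(records, interactions, lnc_pairs)}
        assert got == _brute_force_triads(records, interactions, lnc_pairs)


def test_assembled_triads_are_sorted_and_unique():
    rng = np.random.default_rng(23)
    records, interactions, lnc_pairs = _random_instance(rng, n_per_class=10)
    triads = cerna.assemble_triads(records, interactions + interactions, lnc_pairs)
    keys = [(t.mrna_id, t.mirna_id, t.sponge_id) for t in triads]
    assert keys == sorted(set(keys))


def test_term_post_filter_restricts_core_mrnas():
    records = [_rec("m1", "mRNA", "up"), _rec("m2", "mRNA", "up"),
               _rec("mi1", "miRNA", "down"), _rec("c1", "circRNA", "up")]
    interactions = [_inter("mi1", "m1", "mRNA"), _inter("mi1", "m2", "mRNA"),
                    _inter("mi1", "c1", "circRNA")]
    triads = cerna.assemble_triads(records, interactions, [], keep_mrna_ids={"m2"})
    assert [t.mrna_id for t in triads] == ["m2"]


# ---------------------------------------------------------------------------
# venn overlap


def test_venn_counts_empty_and_single():
    report = cerna.venn_overlap([], [], [])
    assert all(len(v) == 0 for v in report.de_by_class.values())
    records = [_rec("m1", "mRNA", "up"), _rec("mi1", "miRNA", "down")]
    report = cerna.venn_overlap(records, [_inter("mi1", "m1", "mRNA")], [])
    mi_side, m_side = report.overlaps[("miRNA", "mRNA")]
    assert mi_side == {"mi1"}
    assert m_side == {"m1"}


def test_venn_counts_match_set_oracle():
    rng = np.random.default_rng(5)
    records, interactions, lnc_pairs = _random_instance(rng, n_per_class=12)
    report = cerna.venn_overlap(records, interactions, lnc_pairs)
    de = {r.feature_id for r in records if r.status in ("up", "down")}
    cls = {r.feature_id: r.rna_class for r in records}
    for target_class in ("mRNA", "lncRNA", "circRNA"):
        mi_expected = {i.mirna_id for i in interactions
                       if i.target_class == target_class
                       and i.mirna_id in de and i.target_id in de}
        tg_expected = {i.target_id for i in interactions
                       if i.target_class == target_class
                       and i.mirna_id in de and i.target_id in de}
        assert report.overlaps[("miRNA", target_class)] == (mi_expected, tg_expected)
    lnc_expected = {p.lnc_id for p in lnc_pairs if p.lnc_id in de and p.mrna_id in de}
    m_expected = {p.mrna_id for p in lnc_pairs if p.lnc_id in de and p.mrna_id in de}
    assert report.overlaps[("lncRNA", "mRNA")] == (lnc_expected, m_expected)
    for c in report.de_by_class:
        assert report.de_by_class[c] == {f for f in de if cls[f] == c}


# ---------------------------------------------------------------------------
# marker normalization


def _norm_matrix(values: dict, groups):
    df = pd.DataFrame(values).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(
        counts=df.astype(int),
        rna_class=pd.Series(["mRNA"] * len(df), index=df.index),
        group=pd.Series(groups, index=df.columns),
    )


def test_marker_normalize_arithmetic():
    m = _norm_matrix({"t": [8], "a": [2], "b": [8]}, ["cold"])
    f = pd.Series(1.0, index=m.counts.columns)
    out = cerna.marker_normalize(m, f, "t", "a", "b")
    assert out["value"].iloc[0] == pytest.approx(8 / np.sqrt(16))


def test_marker_normalize_self_is_one():
    m = _norm_matrix({"t": [7, 3], "a": [7, 3], "b": [7, 3]}, ["cold", "control"])
    f = pd.Series(1.0, index=m.counts.columns)
    out = cerna.marker_normalize(m, f, "t", "t", "t")
    assert np.allclose(out["value"], 1.0)


def test_marker_normalize_invariant_to_common_sample_scaling():
    rng = np.random.default_rng(2)
    base = rng.integers(5, 50, size=(3, 4))
    scale = np.array([1, 2, 3, 4])
    m1 = _norm_matrix({k: base[i] for i, k in enumerate("tab")},
                      ["cold", "cold", "control", "control"])
    m2 = _norm_matrix({k: base[i] * scale for i, k in enumerate("tab")},
                      ["cold", "cold", "control", "control"])
    f = pd.Series(1.0, index=m1.counts.columns)
    v1 = cerna.marker_normalize(m1, f, "t", "a", "b")["value"]
    v2 = cerna.marker_normalize(m2, f, "t", "a", "b")["value"]
    assert np.allclose(v1, v2)


def test_marker_normalize_product_form():
    m = _norm_matrix({"t": [8], "a": [2], "b": [8]}, ["cold"])
    f = pd.Series(1.0, index=m.counts.columns)
    out = cerna.marker_normalize(m, f, "t", "a", "b", form="product")
    assert out["value"].iloc[0] == pytest.approx(8 / 16)


def test_marker_normalize_zero_marker_names_sample():
    m = _norm_matrix({"t": [8, 8], "a": [2, 0], "b": [8, 8]}, ["cold", "control"])
    f = pd.Series(1.0, index=m.counts.columns)
    with pytest.raises(FormatError, match="s1"):
        cerna.marker_normalize(m, f, "t", "a", "b")


# ---------------------------------------------------------------------------
# group t-test


def test_ttest_identical_groups():
    t, p = cerna.group_ttest([1, 2, 3, 1, 2, 3],
                             ["cold"] * 3 + ["control"] * 3)
    assert (t, p) == (0.0, 1.0)


def test_ttest_strong_separation():
    t, p = cerna.group_ttest([1, 2, 3, 101, 102, 103],
                             ["cold"] * 3 + ["control"] * 3)
    assert p < 1e-4


def test_ttest_degenerate_variance():
    assert cerna.group_ttest([5, 5, 5, 5], ["cold", "cold", "control", "control"]) == (0.0, 1.0)
    with pytest.raises(FormatError, match="zero pooled variance"):
        cerna.group_ttest([5, 5, 6, 6], ["cold", "cold", "control", "control"])


def test_ttest_matches_permutation_oracle():
    # 10-vs-10 keeps the permutation distribution fine-grained enough for a
    # tight comparison with the parametric Student p
    rng = np.random.default_rng(11)
    n = 10
    values = rng.normal(0, 1, size=2 * n) + np.r_[np.zeros(n), np.full(n, 0.9)]
    groups = np.array(["control"] * n + ["cold"] * n)
    t_obs, p_obs = cerna.group_ttest(values, groups)
    n_perm = 100_000
    idx = np.argsort(rng.random((n_perm, 2 * n)), axis=1)
    perms = values[idx]
    x, y = perms[:, :n], perms[:, n:]
    pooled = (x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2
    t_perm = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(pooled * (2 / n))
    p_perm = np.mean(np.abs(t_perm) >= abs(t_obs) - 1e-12)
    assert abs(p_perm - p_obs) < 0.02


def test_sign_concordance_extremes_and_hand_count():
    a = {f"g{i}": v for i, v in enumerate([1.0, -2.0, 0.5, -0.1, 3.0])}
    assert cerna.sign_concordance(a, a) == 1.0
    assert cerna.sign_concordance(a, {k: -v for k, v in a.items()}) == 0.0
    b = {"g0": 2.0, "g1": 1.0, "g2": -0.5, "g3": -4.0, "g4": 0.1}
    # by hand: g0 same, g1 flipped, g2 flipped, g3 same, g4 same -> 3/5
    assert cerna.sign_concordance(a, b) == pytest.approx(3 / 5)
    with pytest.raises(ConsistencyError, match="shared"):
        cerna.sign_concordance({"x": 1.0}, {"y": 1.0})


def test_triad_type_enforces_direction_rules():
    with pytest.raises(FormatError, match="opposite"):
        CeRNATriad(mrna_id="m", mirna_id="i", sponge_id="c", sponge_class="circRNA",
                   mrna_status="up", mirna_status="up", sponge_status="up")
    with pytest.raises(FormatError, match="match"):
        CeRNATriad(mrna_id="m", mirna_id="i", sponge_id="c", sponge_class="circRNA",
                   mrna_status="up", mirna_status="down", sponge_status="down")
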