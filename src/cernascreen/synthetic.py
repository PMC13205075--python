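"""Synthetic two-group transcriptome experiments with a planted truth.

One call to :func:`simulate_experiment` produces everything the pipeline
consumes — counts, feature annotation, sequences, a term catalogue — plus
the :class:`~cernascreen.types.SyntheticTruth` needed to score recovery:

* negative-binomial counts (variance = mu + alpha * mu^2, single global
  alpha) for four RNA classes over two groups of ``n_per_group``
  replicates, baseline means log-uniform in log10 space;
* planted differential features in every class: the group-mean ratio is
  exactly 10^(±planted_log10fc), split symmetrically around the baseline
  (cold mean = base * 10^(+s/2), control mean = base * 10^(-s/2)), which
  keeps each feature's overall expression at its drawn baseline;
* planted ceRNA triads alternating two patterns — (mRNA up, miRNA down,
  circRNA up) and (mRNA down, miRNA up, lncRNA down) — whose miRNA has a
  planted 8mer seed site in both its mRNA and its sponge; lncRNA sponges
  are additionally placed in cis (same chromosome, within the default
  window) of their core mRNA;
* target sequences rejection-sampled so truth miRNAs have **no**
  accidental canonical sites anywhere (non-truth miRNAs may match by
  chance; precision accounting should use the truth);
* one planted enriched term (a "lipid storage" analogue) over planted-up
  mRNAs, plus two adipocyte-marker mRNAs carrying planted up effects so
  marker normalization can be exercised.

Randomness is split per component (design, counts, sequences, terms) from
the master seed by the fixed derivation
``np.random.SeedSequence([seed, component_index])``, so adding or removing
one component never perturbs another's stream.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SimulationError
from . import diffexpr
from .targeting import reverse_complement, seed_sites
from .types import (
    CeRNATriad,
    ExpressionMatrix,
    FeatureAnnotation,
    SimulationConfig,
    SyntheticTruth,
    TermAnnotation,
)

#: fixed component indices for the seed-derivation rule
_COMPONENT = {"design": 0, "counts": 1, "sequences": 2, "terms": 3, "power": 4}

_NUCLEOTIDES = np.array(list("ACGU"))
_CHROMS = [f"chr{i}" for i in range(1, 19)]
_MAX_SEQ_ATTEMPTS = 200


def component_rng(seed: int, component: str) -> np.random.Generator:
    """The package-wide seed-derivation rule (documented and tested)."""
    return np.random.default_rng(np.random.SeedSequence([seed, _COMPONENT[component]]))


# ---------------------------------------------------------------------------
# design: ids, baselines, planted effects, triad membership


def _feature_ids(config: SimulationConfig) -> dict[str, list[str]]:
    return {
        "mRNA": [f"mRNA_{i:05d}" for i in range(config.n_mrna)],
        "lncRNA": [f"lnc_{i:05d}" for i in range(config.n_lncrna)],
        "miRNA": [f"miR_{i:05d}" for i in range(config.n_mirna)],
        "circRNA": [f"circ_{i:05d}" for i in range(config.n_circrna)],
    }


def _plan_design(config: SimulationConfig, rng: np.random.Generator):
    """Choose baselines, DE features, triad membership and marker genes."""
    ids = _feature_ids(config)
    all_ids = [f for cls in ("mRNA", "lncRNA", "miRNA", "circRNA") for f in ids[cls]]
    lo, hi = config.baseline_mean_log10_range
    baseline = pd.Series(10.0 ** rng.uniform(lo, hi, size=len(all_ids)), index=all_ids)

    n_de = dict(config.n_de_per_class)
    de_status: dict[str, tuple[str, float]] = {f: ("ns", 0.0) for f in all_ids}
    perm = {cls: [ids[cls][i] for i in rng.permutation(len(ids[cls]))] for cls in ids}

    n_lnc_triads = config.n_triads // 2
    n_circ_triads = config.n_triads - n_lnc_triads
    fc = config.planted_log10fc

    triads: list[CeRNATriad] = []
    lnc_cursor = 0
    circ_cursor = 0
    for i in range(config.n_triads):
        m = perm["mRNA"][i]
        mu = perm["miRNA"][i]
        if i % 2 == 0 and circ_cursor < n_circ_triads:
            sponge, sponge_class = perm["circRNA"][circ_cursor], "circRNA"
            circ_cursor += 1
            m_dir, mu_dir = "up", "down"
            lnc_mode = "n/a"
        else:
            sponge, sponge_class = perm["lncRNA"][lnc_cursor], "lncRNA"
            lnc_cursor += 1
            m_dir, mu_dir = "down", "up"
            lnc_mode = "cis"
        s_dir = m_dir
        de_status[m] = (m_dir, fc if m_dir == "up" else -fc)
        de_status[mu] = (mu_dir, fc if mu_dir == "up" else -fc)
        de_status[sponge] = (s_dir, fc if s_dir == "up" else -fc)
        triads.append(
            CeRNATriad(
                mrna_id=m, mirna_id=mu, sponge_id=sponge, sponge_class=sponge_class,
                mrna_status=m_dir, mirna_status=mu_dir, sponge_status=s_dir,
                lnc_mode=lnc_mode,
            )
        )

    # remaining planted DE features per class, alternating up/down
    used = {"mRNA": config.n_triads, "miRNA": config.n_triads,
            "lncRNA": lnc_cursor, "circRNA": circ_cursor}
    for cls in ids:
        for j in range(used[cls], n_de.get(cls, 0)):
            f = perm[cls][j]
            direction = "up" if j % 2 == 0 else "down"
            de_status[f] = (direction, fc if direction == "up" else -fc)

    # adipocyte-marker mRNAs: planted up (adipocyte infiltration under cold);
    # only planted when the experiment is non-null
    n_de_mrna = n_de.get("mRNA", 0)
    if n_de_mrna + 2 <= config.n_mrna:
        marker_ids = (perm["mRNA"][n_de_mrna], perm["mRNA"][n_de_mrna + 1])
    else:  # tiny config: fall back to the last two mRNAs
        marker_ids = (perm["mRNA"][-2], perm["mRNA"][-1])
    any_de = any(v > 0 for v in n_de.values())
    if any_de and fc > 0:
        for f in marker_ids:
            de_status[f] = ("up", fc)
            # adipocyte markers are strongly expressed; anchor them in the
            # top of the baseline range so normalization never divides by zero
            baseline[f] = 10.0 ** rng.uniform(hi - 0.25 * (hi - lo), hi)

    normalization_target = next(
        (t.mrna_id for t in triads if t.mrna_status == "down"), None
    )
    return ids, baseline, de_status, triads, marker_ids, normalization_target, perm


# ---------------------------------------------------------------------------
# counts


def _group_means(
    baseline: pd.Series, de_status: dict[str, tuple[str, float]]
) -> tuple[pd.Series, pd.Series]:
    """Expected normalized means (cold, control) per feature."""
    signed = pd.Series({f: s for f, (_, s) in de_status.items()}).loc[baseline.index]
    cold = baseline * 10.0 ** (signed / 2.0)
    control = baseline * 10.0 ** (-signed / 2.0)
    return cold, control


def _draw_counts(
    config: SimulationConfig,
    baseline: pd.Series,
    de_status: dict[str, tuple[str, float]],
    rna_class: pd.Series,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    n = config.n_per_group
    cold_mean, control_mean = _group_means(baseline, de_status)
    samples = [f"control_{j + 1}" for j in range(n)] + [f"cold_{j + 1}" for j in range(n)]
    group = pd.Series(["control"] * n + ["cold"] * n, index=samples)
    mean_matrix = np.column_stack(
        [control_mean.to_numpy()] * n + [cold_mean.to_numpy()] * n
    )
    r = 1.0 / config.dispersion
    p = r / (r + mean_matrix)
    counts = rng.negative_binomial(r, p)
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=baseline.index, columns=samples, dtype=np.int64),
        rna_class=rna_class,
        group=group,
    )


# ---------------------------------------------------------------------------
# annotation


def _make_annotations(
    ids: dict[str, list[str]],
    triads: Sequence[CeRNATriad],
    rng: np.random.Generator,
) -> list[FeatureAnnotation]:
    annotations: dict[str, FeatureAnnotation] = {}
    for cls in ("mRNA", "lncRNA", "miRNA", "circRNA"):
        for fid in ids[cls]:
            chrom = _CHROMS[rng.integers(len(_CHROMS))]
            start = int(rng.integers(1_000, 100_000_000))
            length = int(rng.integers(500, 5_000))
            strand = "+" if rng.random() < 0.5 else "-"
            annotations[fid] = FeatureAnnotation(
                feature_id=fid, rna_class=cls, chrom=chrom,
                start=start, end=start + length, strand=strand,
            )
    # lncRNA sponges move next to their core mRNA (cis planting)
    for t in triads:
        if t.sponge_class != "lncRNA":
            continue
        m = annotations[t.mrna_id]
        gap = int(rng.integers(1_000, 50_000))
        start = m.end + gap
        length = int(rng.integers(500, 5_000))
        old = annotations[t.sponge_id]
        annotations[t.sponge_id] = FeatureAnnotation(
            feature_id=t.sponge_id, rna_class="lncRNA", chrom=m.chrom,
            start=start, end=start + length, strand=old.strand,
        )
    return [annotations[f] for cls in ("mRNA", "lncRNA", "miRNA", "circRNA") for f in ids[cls]]


# ---------------------------------------------------------------------------
# sequences


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return _NUCLEOTIDES[rng.integers(4, size=length)]


def _make_mirna_seqs(
    mirna_ids: Sequence[str], length: int, rng: np.random.Generator
) -> dict[str, str]:
    """miRNAs with pairwise-unambiguous seeds.

    Distinct miRNA families have distinct seeds; beyond plain distinctness,
    no miRNA's 6-nt core may occur inside another's full 8mer site string,
    otherwise a planted site for one miRNA would be an accidental site for
    another and the planted truth would be ill-defined.
    """
    seqs: dict[str, str] = {}
    seen_cores: list[str] = []
    seen_sites: list[str] = []
    for mid in mirna_ids:
        for _ in range(_MAX_SEQ_ATTEMPTS):
            seq = "".join(_random_seq(length, rng))
            core = reverse_complement(seq[1:7])
            site = reverse_complement(seq[1:8]) + "A"
            if any(core in s for s in seen_sites):
                continue
            if any(c in site for c in seen_cores):
                continue
            seen_cores.append(core)
            seen_sites.append(site)
            seqs[mid] = seq
            break
        else:
            raise SimulationError("could not draw miRNAs with unambiguous seed cores")
    return seqs


def _scrub_cores(seq: np.ndarray, cores: Sequence[str], rng: np.random.Generator) -> np.ndarray:
    """Locally re-randomize any occurrence of a forbidden 6-mer core."""
    for _ in range(_MAX_SEQ_ATTEMPTS):
        s = "".join(seq)
        hit = -1
        for core in cores:
            p = s.find(core)
            if p != -1:
                hit = p
                break
        if hit == -1:
            return seq
        seq = seq.copy()
        seq[hit : hit + 6] = _random_seq(6, rng)
    raise SimulationError(
        "could not scrub accidental seed cores; consider longer sequences"
    )


def _make_target_seqs(
    config: SimulationConfig,
    ids: dict[str, list[str]],
    mirna_seqs: dict[str, str],
    triads: Sequence[CeRNATriad],
    scrub_mirnas: Sequence[str],
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[tuple[str, str, int, str]]]:
    lengths = {"mRNA": config.mrna_seq_len, "lncRNA": config.lncrna_seq_len,
               "circRNA": config.circrna_seq_len}
    truth_mirnas = sorted({t.mirna_id for t in triads})
    scrub_mirnas = sorted(set(scrub_mirnas) | set(truth_mirnas))
    core_of = {m: reverse_complement(mirna_seqs[m][1:7]) for m in scrub_mirnas}
    forbidden = [core_of[m] for m in scrub_mirnas]
    # which truth miRNA sites go in which target
    sites_for: dict[str, list[str]] = {}
    for t in triads:
        sites_for.setdefault(t.mrna_id, []).append(t.mirna_id)
        sites_for.setdefault(t.sponge_id, []).append(t.mirna_id)

    seqs: dict[str, str] = {}
    planted: list[tuple[str, str, int, str]] = []
    for cls in ("mRNA", "lncRNA", "circRNA"):
        length = lengths[cls]
        for fid in ids[cls]:
            mirnas_here = sites_for.get(fid, [])
            for _ in range(_MAX_SEQ_ATTEMPTS):
                seq = _scrub_cores(_random_seq(length, rng), forbidden, rng)
                positions: list[tuple[str, int]] = []
                ok = True
                taken: list[tuple[int, int]] = []
                for mid in mirnas_here:
                    site = reverse_complement(mirna_seqs[mid][1:8]) + "A"  # 8mer
                    if length < len(site):
                        raise SimulationError(
                            f"sequence length {length} too short for site insertion"
                        )
                    pos = -1
                    for _ in range(_MAX_SEQ_ATTEMPTS):
                        cand = int(rng.integers(0, length - len(site) + 1))
                        if all(cand + 8 <= a or cand >= b for a, b in taken):
                            pos = cand
                            break
                    if pos == -1:
                        ok = False
                        break
                    seq = seq.copy()
                    seq[pos : pos + 8] = np.array(list(site))
                    taken.append((pos, pos + 8))
                    positions.append((mid, pos))
                if not ok:
                    continue
                s = "".join(seq)
                # verify: each planted miRNA's sites are exactly the planted
                # ones, and every other scrubbed core is absent (insertion
                # boundaries can recreate one)
                expected = {(mid, pos) for mid, pos in positions}
                found = set()
                clean = True
                planted_here = {mid for mid, _ in positions}
                for mid in planted_here:
                    hits = seed_sites(mid, mirna_seqs[mid], fid, s)
                    for h in hits:
                        if (mid, h.position) in expected and h.site_type == "8mer":
                            found.add((mid, h.position))
                        else:
                            clean = False
                    if not clean:
                        break
                if clean:
                    for mid in scrub_mirnas:
                        if mid not in planted_here and s.find(core_of[mid]) != -1:
                            clean = False
                            break
                if clean and found == expected:
                    seqs[fid] = s
                    planted.extend((mid, fid, pos, "8mer") for mid, pos in positions)
                    break
            else:
                raise SimulationError(
                    f"could not place seed sites in {fid}; consider longer sequences"
                )
    return seqs, planted


# ---------------------------------------------------------------------------
# terms


def _make_terms(
    config: SimulationConfig,
    ids: dict[str, list[str]],
    de_status: dict[str, tuple[str, float]],
    rng: np.random.Generator,
) -> tuple[list[TermAnnotation], str | None]:
    namespaces = ["BP", "MF", "CC", "pathway"]
    mrna_ids = ids["mRNA"]
    terms: list[TermAnnotation] = []
    up_mrnas = [f for f in mrna_ids if de_status[f][0] == "up"]
    enriched_id: str | None = None
    if up_mrnas:
        n_core = max(2, int(round(0.7 * len(up_mrnas))))
        core = list(rng.choice(up_mrnas, size=min(n_core, len(up_mrnas)), replace=False))
        background = list(rng.choice(mrna_ids, size=min(5, len(mrna_ids)), replace=False))
        enriched_id = "T_lipid_storage"
        terms.append(
            TermAnnotation(
                term_id=enriched_id, term_name="lipid storage", namespace="BP",
                members=frozenset(core) | frozenset(background),
            )
        )
    for i in range(config.n_terms):
        size = int(rng.integers(10, 51))
        members = frozenset(rng.choice(mrna_ids, size=min(size, len(mrna_ids)), replace=False))
        terms.append(
            TermAnnotation(
                term_id=f"T{i:03d}", term_name=f"synthetic term {i}",
                namespace=namespaces[i % 4], members=members,
            )
        )
    return terms, enriched_id


# ---------------------------------------------------------------------------
# public API


def simulate_experiment(
    config: SimulationConfig,
    with_sequences: bool = True,
    with_terms: bool = True,
) -> tuple[
    ExpressionMatrix,
    list[FeatureAnnotation],
    dict[str, str],
    list[TermAnnotation],
    SyntheticTruth,
]:
    """Generate one complete synthetic experiment with its planted truth.

    Fully reproducible from ``config.seed``. ``with_sequences`` /
    ``with_terms`` can be disabled for count-only studies (e.g. power
    simulation); thanks to the per-component seed split this does not
    change the counts drawn.
    """
    design_rng = component_rng(config.seed, "design")
    (ids, baseline, de_status, triads, marker_ids,
     normalization_target, _perm) = _plan_design(config, design_rng)
    rna_class = pd.Series(
        {f: cls for cls in ids for f in ids[cls]}
    ).loc[baseline.index]
    matrix = _draw_counts(
        config, baseline, de_status, rna_class, component_rng(config.seed, "counts")
    )
    annotations = _make_annotations(ids, triads, design_rng)

    sequences: dict[str, str] = {}
    planted_sites: list[tuple[str, str, int, str]] = []
    if with_sequences:
        seq_rng = component_rng(config.seed, "sequences")
        mirna_seqs = _make_mirna_seqs(ids["miRNA"], config.mirna_seq_len, seq_rng)
        planted_de_mirnas = [
            f for f in ids["miRNA"] if de_status[f][0] in ("up", "down")
        ]
        target_seqs, planted_sites = _make_target_seqs(
            config, ids, mirna_seqs, triads, planted_de_mirnas, seq_rng
        )
        sequences = {**mirna_seqs, **target_seqs}

    terms: list[TermAnnotation] = []
    enriched_id: str | None = None
    if with_terms:
        terms, enriched_id = _make_terms(
            config, ids, de_status, component_rng(config.seed, "terms")
        )

    truth = SyntheticTruth(
        de_status=de_status,
        planted_sites=planted_sites,
        planted_triads=triads,
        marker_ids=marker_ids,
        normalization_target=normalization_target,
        enriched_term_id=enriched_id,
    )
    return matrix, annotations, sequences, terms, truth


def expected_group_means(
    config: SimulationConfig, truth: SyntheticTruth, feature_ids: Sequence[str]
) -> pd.DataFrame:
    """Noiseless expected (cold, control) means implied by the planted design.

    Exposes the infinite-information limit for invariant checks. Baselines
    are re-derived from the design stream, so this matches the simulated
    experiment exactly.
    """
    design_rng = component_rng(config.seed, "design")
    _, baseline, de_status, *_ = _plan_design(config, design_rng)
    cold, control = _group_means(baseline, de_status)
    return pd.DataFrame({"cold": cold.loc[list(feature_ids)],
                         "control": control.loc[list(feature_ids)]})


def power_simulation(
    config: SimulationConfig,
    effect_grid: Sequence[float],
    reps: int,
) -> pd.DataFrame:
    """Detection power of the volcano classification across effect sizes.

    For each planted |log10 FC| in ``effect_grid``, runs ``reps``
    count-only simulations, applies size factors, dispersion estimation,
    the NB Wald test and class-specific classification, and reports the
    fraction of planted features called with their true direction (at
    effect 0, where direction is undefined, any up/down call counts).
    Returns a DataFrame with columns effect, detection_fraction.
    """
    if len(effect_grid) == 0:
        raise FormatError("effect grid must be non-empty")
    if reps < 1:
        raise FormatError("reps must be >= 1")
    rows = []
    seed_rng = component_rng(config.seed, "power")
    for effect in effect_grid:
        detected = 0
        total = 0
        for _ in range(reps):
            rep_seed = int(seed_rng.integers(0, 2**31 - 1))
            rep_config = replace(
                config, planted_log10fc=float(effect), n_triads=0, seed=rep_seed
            )
            matrix, _, _, _, truth = simulate_experiment(
                rep_config, with_sequences=False, with_terms=False
            )
            factors = diffexpr.size_factors(matrix)
            alpha = diffexpr.estimate_dispersion(matrix, factors)
            alpha = diffexpr.moderate_dispersion(alpha, diffexpr.pooled_residual_df(matrix))
            records = diffexpr.nb_wald_test(matrix, factors, alpha)
            records = diffexpr.classify_features(records)
            by_id = {r.feature_id: r for r in records}
            for fid, (direction, _) in truth.de_status.items():
                if direction == "ns":
                    continue
                total += 1
                r = by_id.get(fid)
                if r is None:
                    continue
                if effect == 0:
                    detected += r.status in ("up", "down")
                else:
                    detected += r.status == direction
        rows.append({"effect": float(effect), "detection_fraction": detected / max(total, 1)})
    return pd.DataFrame(rows)
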