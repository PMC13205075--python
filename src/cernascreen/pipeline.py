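"""Stage orchestration: a full screen from counts (or a simulation) to network.

Stages — simulate, de, targets, cerna, enrich, normalize — are plain
functions over a :class:`PipelineConfig`; :func:`run_all` chains them and
records every produced file with a SHA-256 content hash in a JSON
manifest, so identical config + seed reproduces identical hashes. Each
stage communicates with the next only through files, which keeps
subcommand composition equal to ``run_all``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import cerna, diffexpr, enrichment, io_formats, synthetic, targeting
from .errors import ConsistencyError, FormatError
from .types import DERecord, LncTargetPair, Interaction, SimulationConfig

logger = logging.getLogger("cernascreen")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """All paths, thresholds and options of one pipeline run."""

    outdir: str = "results"
    counts: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    fasta: str | None = None
    gmt: str | None = None
    lfc_cut: float = diffexpr.LFC_CUT
    p_cutoffs: dict[str, float] = field(default_factory=lambda: dict(diffexpr.P_CUTOFFS))
    pseudocount: float = diffexpr.DEFAULT_PSEUDOCOUNT
    cis_window: int = targeting.DEFAULT_CIS_WINDOW
    trans_r: float = targeting.DEFAULT_TRANS_R
    circular_scan: bool = False
    min_site_type: str = "7mer-A1"
    dispersion_prior_df: float = 10.0
    normalization_form: str = "geometric"
    normalization_target: str | None = None
    marker_a: str | None = None
    marker_b: str | None = None
    seed: int = 0
    simulate: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lfc_cut <= 0 or self.pseudocount <= 0:
            raise FormatError("thresholds must be positive")
        for cls, p in self.p_cutoffs.items():
            if not 0 < p <= 1:
                raise FormatError(f"p cutoff for {cls} must be in (0, 1]")
        if self.normalization_form not in ("geometric", "product"):
            raise FormatError(f"unknown normalization form {self.normalization_form!r}")
        paths = [p for p in (self.counts, self.metadata, self.annotation, self.fasta, self.gmt) if p]
        if len(set(paths)) != len(paths):
            raise FormatError("input paths must be distinct")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    # -- resolved paths -----------------------------------------------------

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name

    def input_path(self, attribute: str, default_name: str) -> Path:
        configured = getattr(self, attribute)
        if configured:
            return Path(configured)
        candidate = self.path(default_name)
        if candidate.exists():
            return candidate
        raise FormatError(
            f"config field {attribute!r} is unset and {candidate} does not exist "
            "(run the simulate stage first or point the field at an input file)"
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig) -> list[Path]:
    """Generate a synthetic experiment and write every pipeline input."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim_params = dict(config.simulate)
    sim_params.setdefault("seed", config.seed)
    sim_config = SimulationConfig(**sim_params)
    matrix, annotations, sequences, terms, truth = synthetic.simulate_experiment(sim_config)
    files = []
    io_formats.write_counts(matrix, out / "counts.tsv", out / "metadata.tsv")
    files += [out / "counts.tsv", out / "metadata.tsv"]
    io_formats.write_annotations(annotations, out / "annotation.tsv")
    files.append(out / "annotation.tsv")
    io_formats.write_fasta(sequences, out / "sequences.fasta")
    files.append(out / "sequences.fasta")
    io_formats.write_gmt(terms, out / "terms.gmt")
    files.append(out / "terms.gmt")
    truth_de = pd.DataFrame(
        sorted((f, d, s) for f, (d, s) in truth.de_status.items()),
        columns=["feature_id", "direction", "log10_fc"],
    )
    files.append(_write_tsv(truth_de, out / "truth_de.tsv"))
    files.append(_write_tsv(cerna.triad_table(truth.planted_triads), out / "truth_triads.tsv"))
    summary = {
        "marker_ids": list(truth.marker_ids),
        "normalization_target": truth.normalization_target,
        "enriched_term_id": truth.enriched_term_id,
        "n_planted_sites": len(truth.planted_sites),
    }
    with open(out / "truth_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    files.append(out / "truth_summary.json")
    logger.info("simulate: %d features x %d samples, %d planted triads",
                matrix.counts.shape[0], matrix.counts.shape[1], len(truth.planted_triads))
    return files


def _load_matrix(config: PipelineConfig):
    return io_formats.read_counts(
        config.input_path("counts", "counts.tsv"),
        config.input_path("metadata", "metadata.tsv"),
    )


def stage_de(config: PipelineConfig) -> list[Path]:
    """Size factors, dispersion, NB Wald test, classification, PCA."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = _load_matrix(config)
    factors = diffexpr.size_factors(matrix)
    alpha = diffexpr.estimate_dispersion(matrix, factors)
    alpha = diffexpr.moderate_dispersion(
        alpha, diffexpr.pooled_residual_df(matrix), prior_df=config.dispersion_prior_df
    )
    records = diffexpr.nb_wald_test(matrix, factors, alpha, pseudocount=config.pseudocount)
    records = diffexpr.classify_features(records, lfc_cut=config.lfc_cut, p_cutoffs=config.p_cutoffs)
    records = diffexpr.attach_bh(records)
    files = []
    files.append(_write_tsv(diffexpr.de_table(records), out / "de_records.tsv"))
    sf = pd.DataFrame({"sample_id": factors.index, "size_factor": factors.values})
    files.append(_write_tsv(sf, out / "size_factors.tsv"))
    scores, var_frac = diffexpr.pca(matrix, factors)
    pca_df = scores.reset_index(names="sample_id")
    files.append(_write_tsv(pca_df, out / "pca_scores.tsv"))
    vf = pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(var_frac))],
                       "variance_fraction": var_frac})
    files.append(_write_tsv(vf, out / "pca_variance.tsv"))
    n_de = sum(r.status in ("up", "down") for r in records)
    by_class = pd.Series([r.rna_class for r in records if r.status != "ns"]).value_counts()
    logger.info("de: %d features tested, %d differential (%s)",
                len(records), n_de, dict(by_class))
    return files


def _load_de_records(config: PipelineConfig) -> list[DERecord]:
    df = pd.read_csv(Path(config.outdir) / "de_records.tsv", sep="\t")
    return [
        DERecord(
            feature_id=r.feature_id, rna_class=r.rna_class, base_mean=r.base_mean,
            log10_fc=r.log10_fc, se_log=r.se_log, p=r.p, p_adj=r.p_adj, status=r.status,
        )
        for r in df.itertuples(index=False)
    ]


def stage_targets(config: PipelineConfig) -> list[Path]:
    """Seed-site interactions and lncRNA cis/trans relations among DE features."""
    out = Path(config.outdir)
    records = _load_de_records(config)
    de = {r.feature_id: r for r in records if r.status in ("up", "down")}
    sequences = io_formats.read_fasta(config.input_path("fasta", "sequences.fasta"))
    annotations = io_formats.read_annotations(config.input_path("annotation", "annotation.tsv"))
    de_mirnas = {f: sequences[f] for f in de if de[f].rna_class == "miRNA" and f in sequences}
    de_targets = {
        f: sequences[f]
        for f in de
        if de[f].rna_class in ("mRNA", "lncRNA", "circRNA") and f in sequences
    }
    target_classes = {f: de[f].rna_class for f in de_targets}
    interactions: list[Interaction] = []
    if de_mirnas and de_targets:
        interactions = targeting.build_interactions(
            de_mirnas, de_targets, target_classes,
            circular_classes=("circRNA",) if config.circular_scan else (),
            min_site_type=config.min_site_type,
        )
    idf = pd.DataFrame(
        {
            "mirna_id": [i.mirna_id for i in interactions],
            "target_id": [i.target_id for i in interactions],
            "target_class": [i.target_class for i in interactions],
            "n_sites": [i.n_sites for i in interactions],
            "best_site_type": [i.best_site_type for i in interactions],
        }
    )
    files = [_write_tsv(idf, out / "interactions.tsv")]
    ann = {a.feature_id: a for a in annotations}
    lnc_ann = [ann[f] for f in de if de[f].rna_class == "lncRNA" and f in ann]
    mrna_ann = [ann[f] for f in de if de[f].rna_class == "mRNA" and f in ann]
    cis = targeting.lnc_cis_targets(lnc_ann, mrna_ann, window=config.cis_window)
    matrix = _load_matrix(config)
    factors = diffexpr.size_factors(matrix)
    trans = targeting.lnc_trans_targets(
        matrix, factors,
        [a.feature_id for a in lnc_ann], [a.feature_id for a in mrna_ann],
        r_threshold=config.trans_r,
    )
    pdf = pd.DataFrame(
        {
            "lnc_id": [p.lnc_id for p in cis + trans],
            "mrna_id": [p.mrna_id for p in cis + trans],
            "mode": [p.mode for p in cis + trans],
            "evidence": [p.evidence for p in cis + trans],
        }
    )
    files.append(_write_tsv(pdf, out / "lnc_pairs.tsv"))
    logger.info("targets: %d interactions, %d cis + %d trans lnc pairs",
                len(interactions), len(cis), len(trans))
    return files


def _load_interactions(config: PipelineConfig) -> list[Interaction]:
    df = pd.read_csv(Path(config.outdir) / "interactions.tsv", sep="\t")
    return [
        Interaction(
            mirna_id=r.mirna_id, target_id=r.target_id, target_class=r.target_class,
            n_sites=int(r.n_sites), best_site_type=r.best_site_type,
        )
        for r in df.itertuples(index=False)
    ]


def _load_lnc_pairs(config: PipelineConfig) -> list[LncTargetPair]:
    df = pd.read_csv(Path(config.outdir) / "lnc_pairs.tsv", sep="\t")
    return [
        LncTargetPair(lnc_id=r.lnc_id, mrna_id=r.mrna_id, mode=r.mode, evidence=float(r.evidence))
        for r in df.itertuples(index=False)
    ]


def stage_cerna(config: PipelineConfig) -> list[Path]:
    """Venn overlap report, triad assembly, network export."""
    out = Path(config.outdir)
    records = _load_de_records(config)
    interactions = _load_interactions(config)
    lnc_pairs = _load_lnc_pairs(config)
    report = cerna.venn_overlap(records, interactions, lnc_pairs)
    files = [_write_tsv(report.to_frame(), out / "venn_report.tsv")]
    triads = cerna.assemble_triads(records, interactions, lnc_pairs)
    files.append(_write_tsv(cerna.triad_table(triads), out / "triads.tsv"))
    io_formats.write_network(triads, out / "network_edges.tsv", format="edge-TSV")
    files.append(out / "network_edges.tsv")
    io_formats.write_network(triads, out / "network.graphml", format="GraphML")
    files.append(out / "network.graphml")
    logger.info("cerna: %d triads assembled", len(triads))
    return files


def stage_enrich(config: PipelineConfig) -> list[Path]:
    """Up/down mRNA enrichment against the term catalogue, gene-ratio ranked."""
    out = Path(config.outdir)
    records = _load_de_records(config)
    terms = io_formats.read_gmt(config.input_path("gmt", "terms.gmt"))
    universe = {r.feature_id for r in records if r.rna_class == "mRNA"}
    files = []
    for direction in ("up", "down"):
        selected = {
            r.feature_id for r in records if r.rna_class == "mRNA" and r.status == direction
        }
        if selected:
            result = enrichment.enrich(selected, terms, universe, direction_label=direction)
            top = enrichment.top_terms(result)
        else:
            result, top = [], []
        files.append(_write_tsv(
            enrichment.enrichment_table(result, direction), out / f"enrichment_{direction}.tsv"
        ))
        files.append(_write_tsv(
            enrichment.enrichment_table(top, direction), out / f"enrichment_{direction}_top.tsv"
        ))
    logger.info("enrich: universe of %d mRNAs", len(universe))
    return files


def stage_normalize(config: PipelineConfig) -> list[Path]:
    """Marker-gene normalization of the focal gene plus the group t-test."""
    out = Path(config.outdir)
    target, marker_a, marker_b = config.normalization_target, config.marker_a, config.marker_b
    if not (target and marker_a and marker_b):
        summary_path = out / "truth_summary.json"
        if not summary_path.exists():
            raise FormatError(
                "normalization_target / marker_a / marker_b unset and no simulated "
                "truth summary found"
            )
        with open(summary_path) as fh:
            summary = json.load(fh)
        target = target or summary["normalization_target"]
        marker_a = marker_a or summary["marker_ids"][0]
        marker_b = marker_b or summary["marker_ids"][1]
    if target is None:
        raise FormatError("no normalization target available")
    matrix = _load_matrix(config)
    factors = diffexpr.size_factors(matrix)
    values = cerna.marker_normalize(
        matrix, factors, target, marker_a, marker_b, form=config.normalization_form
    )
    t, p = cerna.group_ttest(values["value"], values["group"])
    files = [_write_tsv(values, out / "marker_normalized.tsv")]
    with open(out / "marker_test.json", "w") as fh:
        json.dump(
            {"target": target, "marker_a": marker_a, "marker_b": marker_b,
             "form": config.normalization_form, "t": t, "p": p},
            fh, indent=2, sort_keys=True,
        )
    files.append(out / "marker_test.json")
    logger.info("normalize: %s vs (%s, %s): t=%.3f p=%.4g", target, marker_a, marker_b, t, p)
    return files


def screen_experiment(
    matrix,
    annotations,
    sequences: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> dict[str, Any]:
    """Run the whole screen in memory (no files): counts -> triads.

    Returns a dict with keys ``records`` (classified DERecords),
    ``interactions``, ``lnc_pairs``, ``triads`` and ``venn``. This is the
    same computation the file-based stages perform, exposed for library use.
    """
    config = config or PipelineConfig()
    factors = diffexpr.size_factors(matrix)
    alpha = diffexpr.estimate_dispersion(matrix, factors)
    alpha = diffexpr.moderate_dispersion(
        alpha, diffexpr.pooled_residual_df(matrix), prior_df=config.dispersion_prior_df
    )
    records = diffexpr.nb_wald_test(matrix, factors, alpha, pseudocount=config.pseudocount)
    records = diffexpr.classify_features(
        records, lfc_cut=config.lfc_cut, p_cutoffs=config.p_cutoffs
    )
    records = diffexpr.attach_bh(records)
    de = {r.feature_id: r for r in records if r.status in ("up", "down")}
    de_mirnas = {f: sequences[f] for f in de if de[f].rna_class == "miRNA" and f in sequences}
    de_targets = {
        f: sequences[f] for f in de if de[f].rna_class != "miRNA" and f in sequences
    }
    interactions: list[Interaction] = []
    if de_mirnas and de_targets:
        interactions = targeting.build_interactions(
            de_mirnas, de_targets, {f: de[f].rna_class for f in de_targets},
            circular_classes=("circRNA",) if config.circular_scan else (),
            min_site_type=config.min_site_type,
        )
    ann = {a.feature_id: a for a in annotations}
    lnc_ann = [ann[f] for f in de if de[f].rna_class == "lncRNA" and f in ann]
    mrna_ann = [ann[f] for f in de if de[f].rna_class == "mRNA" and f in ann]
    lnc_pairs = targeting.lnc_cis_targets(lnc_ann, mrna_ann, window=config.cis_window)
    lnc_pairs += targeting.lnc_trans_targets(
        matrix, factors,
        [a.feature_id for a in lnc_ann], [a.feature_id for a in mrna_ann],
        r_threshold=config.trans_r,
    )
    triads = cerna.assemble_triads(records, interactions, lnc_pairs)
    return {
        "records": records,
        "size_factors": factors,
        "interactions": interactions,
        "lnc_pairs": lnc_pairs,
        "triads": triads,
        "venn": cerna.venn_overlap(records, interactions, lnc_pairs),
    }


_STAGES = {
    "simulate": stage_simulate,
    "de": stage_de,
    "targets": stage_targets,
    "cerna": stage_cerna,
    "enrich": stage_enrich,
    "normalize": stage_normalize,
}


def run_all(config: PipelineConfig, simulate: bool = True) -> dict[str, str]:
    """Run every stage in order and write a hash manifest.

    Returns {relative file name: sha256}. Identical config + seed produce an
    identical manifest. Any stage failure aborts with the stage name.
    """
    order = (["simulate"] if simulate else []) + ["de", "targets", "cerna", "enrich", "normalize"]
    produced: list[Path] = []
    for stage in order:
        try:
            produced += _STAGES[stage](config)
        except Exception as exc:
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    manifest = {str(p.relative_to(config.outdir)): _sha256(p) for p in produced}
    manifest_path = Path(config.outdir) / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def render_report(config: PipelineConfig) -> str:
    """Plain-text run summary: per-class DE counts, top triads, marker test."""
    out = Path(config.outdir)
    lines = ["ceRNA screen summary", "===================="]
    de_path = out / "de_records.tsv"
    if de_path.exists():
        df = pd.read_csv(de_path, sep="\t")
        lines.append("\nDifferential features (|log10 FC| >= cut, class p cutoff):")
        for cls, sub in df.groupby("rna_class"):
            up = int((sub["status"] == "up").sum())
            down = int((sub["status"] == "down").sum())
            lines.append(f"  {cls:8s} up={up:5d} down={down:5d} tested={len(sub):6d}")
    triads_path = out / "triads.tsv"
    if triads_path.exists():
        tdf = pd.read_csv(triads_path, sep="\t")
        lines.append(f"\nAssembled ceRNA triads: {len(tdf)}")
        for row in tdf.head(10).itertuples(index=False):
            lines.append(
                f"  {row.mrna_id}({row.mrna_status}) <- {row.mirna_id}({row.mirna_status})"
                f" <- {row.sponge_id}({row.sponge_status}, {row.sponge_class})"
            )
    test_path = out / "marker_test.json"
    if test_path.exists():
        with open(test_path) as fh:
            test = json.load(fh)
        lines.append(
            f"\nMarker normalization: {test['target']} / "
            f"{test['form']}({test['marker_a']}, {test['marker_b']}): "
            f"t={test['t']:.3f}, p={test['p']:.4g}"
        )
    return "\n".join(lines) + "\n"
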