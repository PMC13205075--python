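"""Readers and writers for every external format the pipeline touches.

Formats
-------
counts
    Plain TSV, header row of sample ids, first column feature id, integer
    cells. Dense TSV is deliberate: the target study is six samples by tens
    of thousands of features, where dense is simpler and auditable.
metadata
    TSV with columns ``id``, ``role`` (``sample`` or ``feature``) and
    ``label`` (the group for samples, the RNA class for features).
FASTA
    Standard; T is accepted and normalized to U on read (internal alphabet
    is RNA).
annotation
    TSV with columns feature_id, rna_class, chrom, start, end, strand;
    coordinates 0-based half-open.
GMT
    Standard gene-set lines ``term_id<TAB>description<TAB>member...``. The
    description may carry a namespace prefix ``namespace|name``; plain
    descriptions fall back to ``default_namespace``.
network
    Edge-list TSV or GraphML (via networkx) for assembled ceRNA triads.

Every reader validates against the type invariants and raises
:class:`~cernascreen.errors.FormatError` rather than silently coercing;
write-then-read round-trips are identities.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError
from .types import (
    CeRNATriad,
    ExpressionMatrix,
    FeatureAnnotation,
    TermAnnotation,
    NAMESPACES,
)

_RNA_ALPHABET = set("ACGUN")


# ---------------------------------------------------------------------------
# counts + metadata


def read_counts(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a counts TSV and its sample/feature metadata into an ExpressionMatrix.

    Row and column order are preserved from the file. Raises FormatError on
    duplicate ids or negative/non-integer/missing counts (naming the cell),
    and ConsistencyError when the header or rows disagree with the metadata.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path.name}: duplicate feature ids {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path.name}: duplicate sample ids {dup[:5]}")
    counts = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        for fid, raw in df[col].items():
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
                raise FormatError(
                    f"{path.name}: missing count at feature {fid!r}, sample {col!r}"
                )
            try:
                value = int(raw)
            except ValueError:
                raise FormatError(
                    f"{path.name}: non-integer count {raw!r} at feature {fid!r}, "
                    f"sample {col!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path.name}: negative count {value} at feature {fid!r}, "
                    f"sample {col!r}"
                )
            counts.at[fid, col] = value
    group, rna_class = _read_metadata(metadata_path)
    missing_samples = [s for s in counts.columns if s not in group.index]
    if missing_samples:
        raise ConsistencyError(
            f"samples in {path.name} absent from metadata: {missing_samples}"
        )
    missing_features = [f for f in counts.index if f not in rna_class.index]
    if missing_features:
        raise ConsistencyError(
            f"features in {path.name} absent from metadata: {missing_features[:5]}"
        )
    return ExpressionMatrix(
        counts=counts,
        rna_class=rna_class.loc[counts.index],
        group=group.loc[counts.columns],
    )


def _read_metadata(path: Path) -> tuple[pd.Series, pd.Series]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["id", "role", "label"]
    if list(df.columns) != expected:
        raise FormatError(f"{path.name}: metadata columns must be {expected}")
    samples = df[df["role"] == "sample"]
    features = df[df["role"] == "feature"]
    bad_roles = set(df["role"]) - {"sample", "feature"}
    if bad_roles:
        raise FormatError(f"{path.name}: unknown metadata roles {sorted(bad_roles)}")
    for part, what in ((samples, "sample"), (features, "feature")):
        if part["id"].duplicated().any():
            dup = part["id"][part["id"].duplicated()].tolist()
            raise FormatError(f"{path.name}: duplicate {what} ids {dup[:5]}")
    group = pd.Series(samples["label"].values, index=samples["id"].values)
    rna_class = pd.Series(features["label"].values, index=features["id"].values)
    return group, rna_class


def write_counts(matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path) -> None:
    """Write counts and metadata TSVs that :func:`read_counts` reads back identically."""
    matrix.counts.to_csv(path, sep="\t", index_label="feature_id")
    rows = [("id", "role", "label")]
    rows += [(s, "sample", g) for s, g in matrix.group.items()]
    rows += [(f, "feature", c) for f, c in matrix.rna_class.items()]
    with open(metadata_path, "w", newline="") as fh:
        csv.writer(fh, delimiter="\t", lineterminator="\n").writerows(rows)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: sequence}, uppercased, DNA T normalized to RNA U.

    Duplicate headers, empty sequences and characters outside {A,C,G,U/T,N}
    raise FormatError (with position for illegal characters).
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if current is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path.name}: empty sequence for {current!r}")
        sequences[current] = seq

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current = line[1:].split()[0]
                if not current:
                    raise FormatError(f"{path.name}:{lineno}: empty FASTA header")
                if current in sequences:
                    raise FormatError(f"{path.name}:{lineno}: duplicate header {current!r}")
                chunks = []
            else:
                if current is None:
                    raise FormatError(f"{path.name}:{lineno}: sequence before first header")
                normalized = line.upper().replace("T", "U")
                for i, ch in enumerate(normalized):
                    if ch not in _RNA_ALPHABET:
                        raise FormatError(
                            f"{path.name}:{lineno}: illegal character {line[i]!r} "
                            f"at column {i + 1} in sequence {current!r}"
                        )
                chunks.append(normalized)
    _flush()
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# feature annotation


def read_annotations(path: str | Path) -> list[FeatureAnnotation]:
    """Read the feature-annotation TSV (0-based half-open coordinates)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    expected = ["feature_id", "rna_class", "chrom", "start", "end", "strand"]
    if list(df.columns) != expected:
        raise FormatError(f"{path.name}: annotation columns must be {expected}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            FeatureAnnotation(
                feature_id=row.feature_id,
                rna_class=row.rna_class,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
            )
        )
    ids = [a.feature_id for a in out]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path.name}: duplicate feature ids in annotation")
    return out


def write_annotations(annotations: Iterable[FeatureAnnotation], path: str | Path) -> None:
    rows = [("feature_id", "rna_class", "chrom", "start", "end", "strand")]
    rows += [
        (a.feature_id, a.rna_class, a.chrom, str(a.start), str(a.end), a.strand)
        for a in annotations
    ]
    with open(path, "w", newline="") as fh:
        fh.write("# coordinates are 0-based, half-open\n")
        csv.writer(fh, delimiter="\t", lineterminator="\n").writerows(rows)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path, default_namespace: str = "BP") -> list[TermAnnotation]:
    """Read a GMT gene-set file into TermAnnotation records.

    The description field may encode the namespace as ``namespace|name``
    (the convention :func:`write_gmt` uses); otherwise ``default_namespace``
    applies. Duplicate members within one line collapse to a set. Lines with
    fewer than three fields raise FormatError with the line number.
    """
    path = Path(path)
    terms: list[TermAnnotation] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term_id, description = fields[0], fields[1]
            if "|" in description and description.split("|", 1)[0] in NAMESPACES:
                namespace, name = description.split("|", 1)
            else:
                namespace, name = default_namespace, description
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path.name}:{lineno}: term {term_id!r} has no members")
            key = (namespace, term_id)
            if key in seen:
                raise FormatError(
                    f"{path.name}:{lineno}: duplicate term id {term_id!r} in {namespace}"
                )
            seen.add(key)
            terms.append(
                TermAnnotation(term_id=term_id, term_name=name, namespace=namespace, members=members)
            )
    return terms


def write_gmt(terms: Iterable[TermAnnotation], path: str | Path) -> None:
    """Write terms as GMT with ``namespace|name`` descriptions (sorted members)."""
    with open(path, "w") as fh:
        for t in terms:
            members = "\t".join(sorted(t.members))
            fh.write(f"{t.term_id}\t{t.namespace}|{t.term_name}\t{members}\n")


# ---------------------------------------------------------------------------
# network export

EDGE_MIRNA_MRNA = "mirna_represses_mrna"
EDGE_SPONGE_MIRNA = "sponge_binds_mirna"
EDGE_UNCERTAIN = "lnc_mrna_uncertain"


def _triad_graph(
    triads: Sequence[CeRNATriad],
    extra_edges: Sequence[tuple[str, str, str, str, str]] = (),
) -> nx.DiGraph:
    g = nx.DiGraph()
    for t in triads:
        g.add_node(t.mrna_id, rna_class="mRNA", status=t.mrna_status)
        g.add_node(t.mirna_id, rna_class="miRNA", status=t.mirna_status)
        g.add_node(t.sponge_id, rna_class=t.sponge_class, status=t.sponge_status)
        g.add_edge(t.mirna_id, t.mrna_id, edge_type=EDGE_MIRNA_MRNA)
        g.add_edge(t.sponge_id, t.mirna_id, edge_type=EDGE_SPONGE_MIRNA)
    for src, tgt, edge_type, src_status, tgt_status in extra_edges:
        g.add_node(src, status=src_status)
        g.add_node(tgt, status=tgt_status)
        g.add_edge(src, tgt, edge_type=edge_type)
    return g


def write_network(
    triads: Sequence[CeRNATriad],
    path: str | Path,
    format: str = "edge-TSV",
    extra_edges: Sequence[tuple[str, str, str, str, str]] = (),
) -> None:
    """Write the ceRNA network as an edge-list TSV or GraphML.

    Edge directions follow the regulatory reading: miRNA -> mRNA
    (repression) and sponge -> miRNA (sequestration). ``extra_edges`` allows
    annotated non-triad edges (e.g. a lncRNA–mRNA link whose mechanism is
    uncertain) as (source, target, edge_type, source_status, target_status).
    """
    if format not in ("edge-TSV", "GraphML"):
        raise FormatError(f"unknown network format {format!r}")
    g = _triad_graph(triads, extra_edges)
    if format == "GraphML":
        nx.write_graphml(g, path)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target", "edge_type", "source_status", "target_status"])
        for src, tgt, data in sorted(g.edges(data=True)):
            writer.writerow(
                [
                    src,
                    tgt,
                    data["edge_type"],
                    g.nodes[src].get("status", "ns"),
                    g.nodes[tgt].get("status", "ns"),
                ]
            )
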