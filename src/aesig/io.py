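"""Data model and readers/writers for the expression-decomposition pipeline.

All expression matrices are oriented genes (rows) x samples (columns).
Formats supported: TSV and GCT for expression, TSV for clinical / lymphocyte /
mutation / segment tables, GMT for gene sets, and an HDF5+JSON directory
bundle for trained models.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPRESSION_SPACES = ("raw", "log", "zscore")


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene symbols, one per row of ``values``.
    sample_ids : list of str
        Unique sample identifiers, one per column of ``values``.
    values : ndarray, shape (n_genes, n_samples)
        Finite numeric values.
    space : {"raw", "log", "zscore"}
        Normalization state of the values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    space: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.space not in EXPRESSION_SPACES:
            raise ValueError(f"unknown expression space {self.space!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        if self.space == "zscore" and self.values.size:
            mu = self.values.mean(axis=1)
            sd = self.values.std(axis=1, ddof=1)
            if np.abs(mu).max() > 1e-8 or np.abs(sd - 1).max() > 1e-6:
                raise ValueError(
                    "space='zscore' requires every gene row standardized "
                    "(mean ~0, sd ~1); constant rows must be removed"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, idx], self.space
        )


@dataclass
class CohortClinical:
    """Per-sample clinical table with survival endpoint and covariates.

    ``table`` is indexed by sample id and always carries ``time`` and
    ``event`` columns; ``age``, ``sex``, ``stage``, ``breslow`` and
    ``response`` are optional and may contain missing values.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        for col in ("time", "event"):
            if col not in t.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if (t["time"].dropna() < 0).any():
            raise ValueError("survival time must be non-negative")
        ev = t["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (event)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, sample_ids) -> "CohortClinical":
        return CohortClinical(self.table.loc[list(sample_ids)].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT content)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# expression readers / writers
# ---------------------------------------------------------------------------


def _collapse_duplicate_genes(genes: list[str], values: np.ndarray):
    """Average rows sharing a gene id, keeping first-occurrence order."""
    if len(set(genes)) == len(genes):
        return genes, values
    order: list[str] = []
    rows: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        if g not in rows:
            rows[g] = []
            order.append(g)
        rows[g].append(i)
    out = np.empty((len(order), values.shape[1]))
    for j, g in enumerate(order):
        out[j] = values[rows[g]].mean(axis=0)
    n_dup = len(genes) - len(order)
    logger.info("collapsed %d duplicate gene rows by mean", n_dup)
    return order, out


def _parse_numeric_block(df: pd.DataFrame, path) -> np.ndarray:
    # numpy's string->float cast is correctly rounded (exact text round-trip);
    # fall back to a cell scan only to locate the offending value
    try:
        return df.to_numpy(dtype=str).astype(float)
    except ValueError:
        pass
    raw = df.to_numpy(dtype=str)
    for r in range(raw.shape[0]):
        for c in range(raw.shape[1]):
            try:
                float(raw[r, c])
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {raw[r, c]!r} at gene row "
                    f"{df.index[r]!r}, sample column {df.columns[c]!r}"
                ) from None
    raise FormatError(f"{path}: non-numeric data block")  # pragma: no cover


def read_expression(path, format: str | None = None) -> ExpressionMatrix:
    """Read a gene x sample expression matrix from TSV or GCT.

    Duplicate gene rows are collapsed by arithmetic mean (first-occurrence
    order preserved); duplicate sample columns are a hard error. The
    returned matrix has ``space="raw"``.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format not in ("tsv", "gct"):
        raise ValueError(f"unknown expression format {format!r}")

    with open(path) as fh:
        lines = fh.read().splitlines()
    if format == "gct":
        if len(lines) < 3 or not lines[0].startswith("#1."):
            raise FormatError(f"{path}: not a GCT file (missing version line)")
        lines = lines[2:]
    if not lines:
        raise FormatError(f"{path}: empty file")

    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header has no sample columns")
    drop_desc = format == "gct" and len(header) > 1 and header[1].lower() in (
        "description",
        "desc",
    )
    sample_ids = header[2:] if drop_desc else header[1:]
    dup = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate sample id {dup[0]!r}")

    genes: list[str] = []
    records: list[list[str]] = []
    for ln_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if drop_desc:
            fields = [fields[0]] + fields[2:]
        if len(fields) != len(sample_ids) + 1:
            raise FormatError(
                f"{path}: line {ln_no} has {len(fields)} fields, "
                f"expected {len(sample_ids) + 1}"
            )
        genes.append(fields[0])
        records.append(fields[1:])

    df = pd.DataFrame(records, index=genes, columns=sample_ids)
    values = _parse_numeric_block(df, path)
    genes, values = _collapse_duplicate_genes(genes, values)
    return ExpressionMatrix(genes, list(sample_ids), values, space="raw")


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write a TSV at full precision (bitwise round-trip with read)."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(expr.sample_ids) + "\n")
        for g, row in zip(expr.gene_ids, expr.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# clinical / scores / gene sets
# ---------------------------------------------------------------------------

_CLINICAL_NUMERIC = ("time", "event", "age", "stage", "breslow")


def read_clinical(path) -> CohortClinical:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in _CLINICAL_NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return CohortClinical(df)


def write_clinical(clinical: CohortClinical, path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample_id")


def read_lymphocyte_scores(path) -> pd.Series:
    """Two-column TSV: sample id, infiltration score."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: expected a score column")
    s = pd.to_numeric(df.iloc[:, 0], errors="raise")
    s.index = s.index.astype(str)
    return s


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name <TAB> description <TAB> gene ...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {ln_no} has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


# ---------------------------------------------------------------------------
# model bundle
# ---------------------------------------------------------------------------

BUNDLE_VERSION = 1


def _weights_digest(models: dict) -> str:
    h = hashlib.md5()
    for name in sorted(models):
        model = models[name]
        for arr in model.parameters():
            h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
    return h.hexdigest()


def save_model(bundle, path) -> None:
    """Persist a trained :class:`~aesig.workflow.ModelBundle` to a directory.

    Weights go to ``weights.h5``; gene panels, node indices, orientation,
    config and a weight checksum go to ``meta.json`` so panels can never be
    separated from the weights they were trained on.
    """
    import h5py

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    models = {name: sig.model for name, sig in bundle.signatures.items()}
    for m in models.values():
        if not m.trained:
            raise ValueError("refusing to save an untrained model")

    with h5py.File(path / "weights.h5", "w") as h5:
        for name, model in models.items():
            grp = h5.create_group(name)
            for i, (w, b) in enumerate(zip(model.enc_W, model.enc_b)):
                grp.create_dataset(f"enc_W{i}", data=w)
                grp.create_dataset(f"enc_b{i}", data=b)
            for i, (w, b) in enumerate(zip(model.dec_W, model.dec_b)):
                grp.create_dataset(f"dec_W{i}", data=w)
                grp.create_dataset(f"dec_b{i}", data=b)

    meta = {
        "version": BUNDLE_VERSION,
        "checksum": _weights_digest(models),
        "config": bundle.config,
        "seed": bundle.seed,
        "signatures": {
            name: {
                "compartment": sig.compartment,
                "node_index": int(sig.node_index),
                "orientation": int(sig.orientation),
                "panel": list(sig.panel),
                "layer_sizes": [int(s) for s in sig.model.layer_sizes],
                "linear_bottleneck": bool(sig.model.linear_bottleneck),
                "gene_weights": {
                    g: float(v) for g, v in sig.gene_weights.items()
                },
                "selection_stats": sig.selection_stats.to_dict(orient="list"),
            }
            for name, sig in bundle.signatures.items()
        },
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(path):
    """Load a model bundle saved by :func:`save_model`.

    Raises
    ------
    FormatError
        On version mismatch, missing files, or checksum failure.
    """
    import h5py

    from .autoencoder import AutoencoderModel
    from .workflow import ModelBundle, TrainedSignature

    path = Path(path)
    meta_path = path / "meta.json"
    h5_path = path / "weights.h5"
    if not meta_path.exists() or not h5_path.exists():
        raise FormatError(f"{path}: not a model bundle (missing files)")
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("version") != BUNDLE_VERSION:
        raise FormatError(
            f"{path}: bundle version {meta.get('version')} != {BUNDLE_VERSION}"
        )

    signatures = {}
    models = {}
    try:
        with h5py.File(h5_path, "r") as h5:
            for name, sig_meta in meta["signatures"].items():
                grp = h5[name]
                n_enc = len(sig_meta["layer_sizes"]) - 1
                enc_W = [grp[f"enc_W{i}"][()] for i in range(n_enc)]
                enc_b = [grp[f"enc_b{i}"][()] for i in range(n_enc)]
                dec_W = [grp[f"dec_W{i}"][()] for i in range(n_enc)]
                dec_b = [grp[f"dec_b{i}"][()] for i in range(n_enc)]
                model = AutoencoderModel(
                    layer_sizes=sig_meta["layer_sizes"],
                    enc_W=enc_W,
                    enc_b=enc_b,
                    dec_W=dec_W,
                    dec_b=dec_b,
                    linear_bottleneck=sig_meta["linear_bottleneck"],
                    trained=True,
                )
                models[name] = model
                signatures[name] = TrainedSignature(
                    compartment=sig_meta["compartment"],
                    model=model,
                    panel=list(sig_meta["panel"]),
                    node_index=int(sig_meta["node_index"]),
                    orientation=int(sig_meta["orientation"]),
                    gene_weights=pd.Series(sig_meta["gene_weights"]),
                    selection_stats=pd.DataFrame(sig_meta["selection_stats"]),
                )
    except (KeyError, OSError) as exc:
        raise FormatError(f"{path}: truncated or corrupted bundle: {exc}") from exc

    if _weights_digest(models) != meta["checksum"]:
        raise FormatError(f"{path}: weight checksum mismatch (corrupted bundle)")
    return ModelBundle(
        signatures=signatures, config=meta.get("config", {}), seed=meta.get("seed")
    )


# ---------------------------------------------------------------------------
# mutation / segment tables
# ---------------------------------------------------------------------------


def read_segments(path) -> dict[str, list[tuple[float, float]]]:
    """Read a copy-number segment TSV into per-sample (copy, length) lists.

    Columns: sample, chrom, start, end, copy_number. Fragment length is
    ``end - start`` (half-open coordinates).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "start", "end", "copy_number"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing segment columns {sorted(missing)}")
    profiles: dict[str, list[tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        length = float(row.end) - float(row.start)
        if length <= 0:
            raise FormatError(f"{path}: non-positive segment length for {row.sample}")
        profiles.setdefault(str(row.sample), []).append(
            (float(row.copy_number), length)
        )
    return profiles


def read_mutation_table(path) -> pd.DataFrame:
    """Read a MAF-like TSV with at least sample and variant classification."""
    df = pd.read_csv(path, sep="\t")
    colmap = {}
    for cand in ("sample", "Tumor_Sample_Barcode"):
        if cand in df.columns:
            colmap[cand] = "sample"
            break
    for cand in ("variant_classification", "Variant_Classification"):
        if cand in df.columns:
            colmap[cand] = "variant_classification"
            break
    df = df.rename(columns=colmap)
    required = {"sample", "variant_classification"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing mutation columns {sorted(missing)}")
    df["sample"] = df["sample"].astype(str)
    return df
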