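"""Tab-separated file formats for every pipeline artifact.

All artifacts are plain TSV: diffable, language-neutral, round-trip exact
(floats written with 17 significant digits). Signature files carry their
scalar metadata (global shift, permutation p, seed) as commented
``# key=value`` header lines.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ATLAS_COLUMNS, RegionAtlas
from .connectome import n_pairs, pair_labels
from .cwas import CohortDataset, PHENOTYPE_COLUMNS, SignatureMap
from .exceptions import IntegrityError, SchemaError
from .expression import ExpressionPanel

FLOAT_FMT = "%.17g"


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} missing column(s): {missing}")


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write a TSV, optionally preceded by ``# key=value`` metadata lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by :func:`write_table`; returns (frame, metadata)."""
    metadata: dict[str, str] = {}
    lines = Path(path).read_text().splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            stripped = line[1:].strip()
            if "=" in stripped:
                key, value = stripped.split("=", 1)
                metadata[key.strip()] = value.strip()
        else:
            break
    df = pd.read_csv(
        _io.StringIO("".join(lines[body_start:])), sep="\t",
        float_precision="round_trip",
    )
    return df, metadata


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    write_table(atlas.table, path)


def read_atlas(path: str | Path) -> RegionAtlas:
    df, _ = read_table(path)
    _require_columns(df, ATLAS_COLUMNS, "atlas table")
    return RegionAtlas(df)


def write_connectomes(dataset: CohortDataset, path: str | Path) -> None:
    """One row per subject: subject_id then the L canonical columns c<i>_<j>."""
    r = int((np.sqrt(8 * dataset.n_connections + 1) - 1) // 2)
    df = pd.DataFrame(dataset.connectomes, columns=pair_labels(r))
    df.insert(0, "subject_id", dataset.phenotypes["subject_id"].to_numpy())
    write_table(df, path)


def read_connectomes(path: str | Path) -> pd.DataFrame:
    df, _ = read_table(path)
    _require_columns(df, ["subject_id"], "connectome table")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise IntegrityError(f"duplicate subject_id: {dupes[:5]}")
    n_cols = df.shape[1] - 1
    r = int((np.sqrt(8 * n_cols + 1) - 1) // 2)
    expected = pair_labels(r)
    if n_pairs(r) != n_cols or list(df.columns[1:]) != expected:
        raise SchemaError("connectome columns are not the canonical c<i>_<j> layout")
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    _require_columns(phenotypes, PHENOTYPE_COLUMNS, "phenotype table")
    write_table(phenotypes, path)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df, _ = read_table(path)
    _require_columns(df, PHENOTYPE_COLUMNS, "phenotype table")
    if df["subject_id"].duplicated().any():
        raise IntegrityError("duplicate subject_id in phenotypes")
    return df


def read_cohort(
    connectome_path: str | Path, phenotype_path: str | Path, contrast_name: str = "contrast"
) -> CohortDataset:
    """Assemble a cohort from its connectome and phenotype files."""
    conn = read_connectomes(connectome_path)
    pheno = read_phenotypes(phenotype_path)
    merged = pheno.merge(conn[["subject_id"]], on="subject_id", how="inner")
    if len(merged) != len(pheno) or len(merged) != len(conn):
        raise IntegrityError("subject_id mismatch between phenotypes and connectomes")
    conn = conn.set_index("subject_id").loc[pheno["subject_id"]]
    return CohortDataset(
        phenotypes=pheno.reset_index(drop=True),
        connectomes=conn.to_numpy(dtype=float),
        contrast_name=contrast_name,
    )


def write_signature(sig: SignatureMap, path: str | Path) -> None:
    write_table(
        sig.to_frame(),
        path,
        metadata={
            "contrast_name": sig.contrast_name,
            "global_shift": repr(sig.global_shift),
            "global_shift_p": repr(sig.global_shift_p),
            "n_perm": sig.n_perm,
            "seed": sig.seed,
            "q_threshold": repr(sig.q_threshold),
        },
    )


def read_signature(path: str | Path) -> SignatureMap:
    df, meta = read_table(path)
    _require_columns(df, ["beta", "t", "p", "q", "sig", "cohens_d"], "signature table")
    none_or = lambda v, cast: None if v in (None, "None") else cast(v)
    return SignatureMap(
        beta=df["beta"].to_numpy(),
        t=df["t"].to_numpy(),
        p=df["p"].to_numpy(),
        q=df["q"].to_numpy(),
        sig_mask=df["sig"].to_numpy(dtype=bool),
        cohens_d=df["cohens_d"].to_numpy(),
        global_shift=float(meta.get("global_shift", "nan")),
        global_shift_p=none_or(meta.get("global_shift_p"), float),
        n_perm=int(meta.get("n_perm", 0)),
        seed=none_or(meta.get("seed"), int),
        q_threshold=float(meta.get("q_threshold", 0.05)),
        contrast_name=meta.get("contrast_name", "contrast"),
    )


def write_expression_samples(samples: pd.DataFrame, path: str | Path) -> None:
    _require_columns(samples, ["donor_id", "sample_id", "region_id"], "sample table")
    write_table(samples, path)


def read_expression_samples(path: str | Path) -> pd.DataFrame:
    df, _ = read_table(path)
    _require_columns(df, ["donor_id", "sample_id", "region_id"], "sample table")
    return df


def write_panel(panel: ExpressionPanel, path: str | Path) -> None:
    write_table(panel.to_frame(), path)


def read_panel(path: str | Path) -> ExpressionPanel:
    df, _ = read_table(path)
    _require_columns(df, ["region_id"], "expression panel")
    genes = [c for c in df.columns if c != "region_id"]
    return ExpressionPanel(X=df[genes].to_numpy(dtype=float), genes=genes)


def read_gene_set(path: str | Path) -> list[str]:
    """Gene-set file: one gene name per line, blanks ignored."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
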