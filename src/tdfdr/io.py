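"""Table ingestion, compositional preprocessing, and result serialization.

Feature tables arrive as dense TSV/CSV with features as rows or columns;
orientation is auto-detected by overlap between table labels and the
metadata's sample IDs.  The preprocessing helpers implement the standard
microbiome pipeline: a prevalence filter on raw counts followed by a
centered log-ratio transform with a pseudocount.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CutoffSearchResult
from .data import ConfounderMatrix, CovariateVector, FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_tables",
    "prevalence_filter",
    "clr_transform",
    "write_results",
    "write_feature_table",
]


def _read_any(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def _infer_kind(s: pd.Series) -> str:
    if not pd.api.types.is_numeric_dtype(s):
        return "categorical"
    vals = np.unique(s.dropna().to_numpy())
    if len(vals) == 2 and set(vals) <= {0, 1}:
        return "binary"
    return "continuous"


def read_tables(
    feature_path,
    metadata_path,
    covariate: str,
    confounders: list[str],
    orientation: str = "auto",
    outcome_family: str = "gaussian",
):
    """Load and align a feature table and sample metadata.

    Returns validated ``(FeatureMatrix, CovariateVector, ConfounderMatrix)``
    restricted to the samples present in both tables with complete covariate
    and confounder values.

    ``orientation``: "auto" detects whether features are rows or columns by
    sample-ID overlap with the metadata index; "features_as_rows" /
    "samples_as_rows" force it.
    """
    feats = _read_any(feature_path)
    meta = _read_any(metadata_path)
    meta.index = meta.index.astype(str)
    feats.index = feats.index.astype(str)
    feats.columns = feats.columns.astype(str)

    for col in [covariate, *confounders]:
        if col not in meta.columns:
            raise ValueError(f"column {col!r} not found in metadata")

    samples = set(meta.index)
    if orientation == "auto":
        col_overlap = len(samples & set(feats.columns))
        row_overlap = len(samples & set(feats.index))
        orientation = (
            "features_as_rows" if col_overlap >= row_overlap else "samples_as_rows"
        )
    if orientation == "features_as_rows":
        feats = feats.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    if feats.index.duplicated().any():
        raise ValueError("duplicate sample ids in feature table")
    if feats.columns.duplicated().any():
        raise ValueError("duplicate feature ids in feature table")

    shared = [s for s in feats.index if s in samples]
    if not shared:
        raise ValueError("no overlapping samples between feature table and metadata")
    meta = meta.loc[shared]
    feats = feats.loc[shared]

    complete = meta[[covariate, *confounders]].notna().all(axis=1)
    if not complete.all():
        dropped = meta.index[~complete].tolist()
        logger.warning(
            "dropping %d sample(s) with missing covariate/confounder values: %s",
            len(dropped), dropped[:10],
        )
        meta = meta.loc[complete]
        feats = feats.loc[complete]

    x = meta[covariate]
    X = CovariateVector(x.to_numpy(), kind=_infer_kind(x))
    kinds = [
        "categorical" if _infer_kind(meta[c]) == "categorical" else "continuous"
        for c in confounders
    ]
    zvals = np.column_stack(
        [
            meta[c].to_numpy()
            if kinds[i] == "categorical"
            else meta[c].to_numpy(dtype=float)
            for i, c in enumerate(confounders)
        ]
    )
    Z = ConfounderMatrix(zvals, kinds=kinds)
    Y = FeatureMatrix(
        feats.to_numpy(dtype=float), list(feats.columns), outcome_family
    )
    return Y, X, Z


def prevalence_filter(counts: FeatureMatrix, min_prevalence: float) -> FeatureMatrix:
    """Drop features present (nonzero) in strictly less than ``min_prevalence``
    of the samples; a feature at exactly the threshold is kept."""
    if not (0 < min_prevalence < 1):
        raise ValueError("min_prevalence must be in (0, 1)")
    if (counts.values < 0).any():
        raise ValueError("prevalence filter expects non-negative counts")
    prev = (counts.values > 0).mean(axis=0)
    keep = prev >= min_prevalence
    logger.info(
        "prevalence filter at %.3f: %d of %d features retained",
        min_prevalence, int(keep.sum()), counts.m,
    )
    return FeatureMatrix(
        counts.values[:, keep],
        [counts.feature_ids[j] for j in np.nonzero(keep)[0]],
        counts.outcome_family,
    )


def clr_transform(counts: FeatureMatrix, pseudocount: float = 0.5) -> FeatureMatrix:
    """Centered log-ratio transform per sample: log(count + pseudocount) minus
    the sample's mean log value, so each output row sums to zero."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (counts.values < 0).any():
        raise ValueError("clr expects non-negative counts")
    logs = np.log(counts.values + pseudocount)
    out = logs - logs.mean(axis=1, keepdims=True)
    return FeatureMatrix(out, list(counts.feature_ids), "gaussian")


def results_frame(
    feature_ids: list[str],
    res2d: CutoffSearchResult | None = None,
    res1d: CutoffSearchResult | None = None,
    bh_rejected: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-feature result table: statistics plus rejection flags per procedure."""
    m = len(feature_ids)
    base = res2d or res1d
    if base is None or base.stats is None:
        raise ValueError("need at least one result carrying statistics")
    full_tm = np.full(m, np.nan)
    full_tc = np.full(m, np.nan)
    kept = [j for j in range(m) if base.dropped_features is None
            or j not in set(base.dropped_features.tolist())]
    full_tm[kept] = base.stats.t_marginal
    full_tc[kept] = base.stats.t_conditional
    df = pd.DataFrame(
        {"feature_id": feature_ids, "t_marginal": full_tm, "t_conditional": full_tc}
    )
    if res2d is not None:
        df["rejected_2d"] = np.isin(np.arange(m), res2d.rejected)
    if res1d is not None:
        df["rejected_1d"] = np.isin(np.arange(m), res1d.rejected)
    if bh_rejected is not None:
        df["rejected_bh"] = np.isin(np.arange(m), bh_rejected)
    return df


def write_results(
    outdir,
    feature_ids: list[str],
    res2d: CutoffSearchResult | None = None,
    res1d: CutoffSearchResult | None = None,
    bh_rejected: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Write the per-feature TSV and a JSON run-metadata sidecar; returns both paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = results_frame(feature_ids, res2d, res1d, bh_rejected)
    table_path = outdir / "results.tsv"
    df.to_csv(table_path, sep="\t", index=False)
    meta = {}
    for name, res in (("2d", res2d), ("1d", res1d)):
        if res is None:
            continue
        meta[name] = {
            "t1_star": float(res.t1_star),
            "t2_star": float(res.t2_star),
            "n_rejections": int(res.n_rejections),
            "fdp_at_optimum": float(res.fdp_at_optimum),
            "pi0": float(res.pi0),
            **{k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
               for k, v in res.params.items()},
        }
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=1, default=str))
    return table_path, meta_path


def write_feature_table(path, Y: FeatureMatrix, sample_ids=None) -> Path:
    """Export a FeatureMatrix to TSV (features as columns), round-trippable
    through ``read_tables``."""
    path = Path(path)
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(Y.n)]
    pd.DataFrame(Y.values, index=sample_ids, columns=Y.feature_ids).to_csv(
        path, sep="\t"
    )
    return path
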