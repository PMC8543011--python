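"""Readers and writers for the text formats the pipeline exchanges.

Flow events travel as CSV with a header row (one column per channel
plus sample/condition/inhibitor metadata), bulk matrices as TSV with a
samplesheet sidecar, single-cell data as MatrixMarket plus
features/barcodes sidecars, and ground truth / reports as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from . import flow
from .flow import ChannelError, ConfigurationError, EventTable
from .synthetic import BulkExpressionPair

_META_COLUMNS = ("sample_id", "condition", "inhibitor")


def arcsinh_transform(values: np.ndarray, cofactor: float = 150.0) -> np.ndarray:
    """Standard arcsinh(x / cofactor) display transform for flow intensities."""
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


def write_events_csv(table: EventTable, path: str | Path) -> Path:
    """Write an event table (channels + metadata columns) to CSV."""
    path = Path(path)
    out = table.data.copy()
    out["sample_id"] = table.sample_id
    out["condition"] = table.condition
    out["inhibitor"] = table.inhibitor
    out.to_csv(path, index=False)
    return path


def read_events(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
    transform: str | None = None,
    cofactor: float = 150.0,
    sample_id: str | None = None,
    condition: str | None = None,
    inhibitor: str | None = None,
) -> EventTable:
    """Read a delimited event table into an :class:`EventTable`.

    ``channel_map`` renames file columns to panel channel names.
    ``transform="arcsinh"`` applies arcsinh(x/cofactor) to the channel
    columns for files holding raw intensities; by default values are
    taken as already transformed.  Metadata may come from columns or be
    passed explicitly.
    """
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if channel_map:
        df = df.rename(columns=dict(channel_map))
    missing = [c for c in flow.ALL_CHANNELS if c not in df.columns]
    if missing:
        raise ChannelError(f"{path.name}: missing channels {missing}")
    meta = {}
    for key, override in zip(_META_COLUMNS, (sample_id, condition, inhibitor)):
        if override is not None:
            meta[key] = override
        elif key in df.columns:
            values = df[key].unique()
            if len(values) != 1:
                raise ConfigurationError(
                    f"{path.name}: column {key!r} is not constant; split per sample"
                )
            meta[key] = str(values[0])
        else:
            meta[key] = {"sample_id": "unknown", "condition": "alone", "inhibitor": "none"}[key]
    data = df[list(flow.ALL_CHANNELS)].astype(float)
    if transform == "arcsinh":
        data = data.apply(lambda col: arcsinh_transform(col.to_numpy(), cofactor))
    elif transform is not None:
        raise ConfigurationError(f"unknown transform {transform!r}")
    return EventTable(
        data=data.reset_index(drop=True),
        sample_id=meta["sample_id"],
        condition=meta["condition"],
        inhibitor=meta["inhibitor"],
    )


def read_samplesheet(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated samplesheet."""
    return pd.read_csv(path, sep="\t")


def write_bulk(pair: BulkExpressionPair, matrix_path: str | Path, samples_path: str | Path) -> None:
    """Write a bulk matrix (genes × samples TSV) and its samplesheet."""
    pair.matrix.to_csv(matrix_path, sep="\t")
    pair.samples.to_csv(samples_path, sep="\t", index=False)


def read_bulk(matrix_path: str | Path, samples_path: str | Path) -> BulkExpressionPair:
    """Read a bulk matrix TSV (gene rows) and samplesheet TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    required = {"sample", "patient", "condition"}
    missing = required - set(samples.columns)
    if missing:
        raise ConfigurationError(f"samplesheet missing columns: {sorted(missing)}")
    return BulkExpressionPair(matrix=matrix, samples=samples)


def write_sc_mtx(adata: ad.AnnData, out_dir: str | Path) -> Path:
    """Write cells × genes counts as MatrixMarket with TSV sidecars.

    Follows the genes × cells on-disk convention with ``features.tsv``
    and ``barcodes.tsv`` sidecars; per-cell metadata goes to ``meta.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scipy_io.mmwrite(str(out_dir / "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names).to_csv(out_dir / "features.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out_dir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(out_dir / "meta.tsv", sep="\t")
    return out_dir


def read_sc_mtx(in_dir: str | Path) -> ad.AnnData:
    """Read an MTX directory written by :func:`write_sc_mtx` (or 10x-style)."""
    in_dir = Path(in_dir)
    X = sparse.csr_matrix(scipy_io.mmread(in_dir / "matrix.mtx").T)
    features = pd.read_csv(in_dir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(in_dir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell"))
    meta_path = in_dir / "meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        obs = meta.loc[obs.index]
    return ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(features, name="gene"))
    )


def read_sc_dense(path: str | Path) -> ad.AnnData:
    """Read a dense cells × genes TSV into an AnnData."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ad.AnnData(
        X=sparse.csr_matrix(df.to_numpy(dtype=float)),
        obs=pd.DataFrame(index=df.index),
        var=pd.DataFrame(index=df.columns),
    )


def jsonable(obj):
    """Recursively convert configs/results to JSON-serializable structures."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {_jskey(k): jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _jskey(key):
    if isinstance(key, (frozenset, set)):
        return "+".join(sorted(key)) if key else "all-negative"
    if isinstance(key, tuple):
        return "|".join(str(k) for k in key)
    return str(key)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path
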