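"""Reading and writing the delimited-text and weight-file formats.

Expression and measurement tables are UTF-8 CSV/TSV (delimiter sniffed)
with one header row and one identifier column.  The canonical in-memory
orientation is samples in rows; files shipping genes in rows (the usual
layout of tumor compendia) are auto-detected and transposed.  Network
weights round-trip bit-exactly through an HDF5 container whose header
embeds layer dimensions and provenance.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MeasurementTable
from .networks import AutoencoderSpec, AutoencoderWeights, EncoderState, PredictorState

logger = logging.getLogger("transcell")

_MISSING_TOKENS = {"", "na", "nan"}
_GENE_HINTS = ("gene", "symbol", "hugo")
_SAMPLE_HINTS = ("sample", "cell", "line", "model", "depmap", "patient", "barcode")
# bare human gene symbols: upper-case letters/digits, possibly '-' or '.', e.g. TP53, NKX2-1
_GENE_SYMBOL_RE = re.compile(r"^[A-Z][A-Z0-9\-\.]{0,14}$")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    # header parsed manually: pandas would rename duplicated column ids,
    # hiding duplicate gene symbols from the collapse logic
    raw = pd.read_csv(
        path, sep=None, engine="python", header=None, dtype=str, keep_default_na=False
    )
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise ValueError(f"{path} contains no data rows/columns")
    header = raw.iloc[0].astype(str)
    df = raw.iloc[1:, 1:].copy()
    df.columns = pd.Index(header.iloc[1:].tolist(), name=None)
    df.index = pd.Index(raw.iloc[1:, 0].astype(str).tolist(), name=header.iloc[0])
    return df


def _to_numeric(df: pd.DataFrame, path, allow_missing: bool) -> pd.DataFrame:
    out = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df.iloc[:, j], errors="coerce").to_numpy()
        bad = np.isnan(converted)
        if bad.any():
            tokens = np.array([str(v).strip().lower() for v in raw[:, j]])
            is_missing = np.isin(tokens, list(_MISSING_TOKENS))
            offending = bad & ~is_missing
            if offending.any():
                i = int(np.flatnonzero(offending)[0])
                raise ValueError(
                    f"{path}: non-numeric value {raw[i, j]!r} at row {df.index[i]!r}, "
                    f"column {col!r}"
                )
            if not allow_missing and is_missing.any():
                i = int(np.flatnonzero(is_missing)[0])
                raise ValueError(
                    f"{path}: missing value at row {df.index[i]!r}, column {col!r}; "
                    "expression matrices must be complete"
                )
        out[:, j] = converted
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _looks_gene_like(ids) -> float:
    ids = list(ids)
    if not ids:
        return 0.0
    return sum(bool(_GENE_SYMBOL_RE.match(str(i))) for i in ids) / len(ids)


def _infer_rows_are(df: pd.DataFrame) -> str:
    name = (df.index.name or "").lower()
    if any(h in name for h in _GENE_HINTS):
        return "genes"
    if any(h in name for h in _SAMPLE_HINTS):
        return "samples"
    row_score = _looks_gene_like(df.index)
    col_score = _looks_gene_like(df.columns)
    if row_score > col_score:
        return "genes"
    return "samples"


def read_expression(path, orientation: str = "auto") -> ExpressionMatrix:
    """Read an expression matrix, returning the canonical samples-in-rows form.

    ``orientation`` is "samples", "genes" (what the file's ROWS are) or
    "auto" (header keywords, then a gene-symbol heuristic on the
    identifiers).  Duplicate gene entries collapse to the first occurrence
    with a logged warning; duplicate sample ids are an error.
    """
    if orientation not in ("auto", "samples", "genes"):
        raise ValueError("orientation must be 'auto', 'samples' or 'genes'")
    df = _read_table(path)
    df = _to_numeric(df, path, allow_missing=False)
    rows_are = orientation if orientation != "auto" else _infer_rows_are(df)
    if rows_are == "genes":
        df = df.T  # now samples x genes

    # duplicate genes collapse by first occurrence; duplicate samples are fatal
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        logger.warning(
            "collapsing %d duplicated gene identifiers by first occurrence: %s",
            len(dups),
            dups[:10],
        )
        df = df.loc[:, ~df.columns.duplicated()]
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate sample identifiers: {dups[:10]}")
    return ExpressionMatrix.from_frame(df)


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    df = expr.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def read_measurements(path, measurement_type: str) -> MeasurementTable:
    """Read a samples x features measurement table.

    Empty strings, "NA" and "NaN" (case-insensitive) mark missing values;
    mutation tables must otherwise contain only 0/1.
    """
    df = _read_table(path)
    df = _to_numeric(df, path, allow_missing=True)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate identifiers in measurement table")
    return MeasurementTable(
        sample_ids=list(df.index),
        feature_ids=list(df.columns),
        values=df.to_numpy(),
        measurement_type=measurement_type,
    )


def write_measurements(meas: MeasurementTable, path, sep: str = "\t") -> None:
    df = meas.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# weight persistence
# ---------------------------------------------------------------------------


def _write_layers(group, layers) -> None:
    for i, (W, b) in enumerate(layers):
        g = group.create_group(f"layer{i}")
        g.create_dataset("W", data=np.asarray(W, dtype=np.float64))
        g.create_dataset("b", data=np.asarray(b, dtype=np.float64))


def _read_layers(group):
    layers = []
    for i in range(len(group)):
        g = group[f"layer{i}"]
        layers.append([g["W"][()], g["b"][()]])
    return layers


def _spec_header(spec: AutoencoderSpec) -> dict:
    return {
        "input_dim": spec.input_dim,
        "hidden_dim": spec.hidden_dim,
        "bottleneck_dim": spec.bottleneck_dim,
        "alpha": spec.alpha,
    }


def save_weights(state, path) -> None:
    """Persist an EncoderState, AutoencoderWeights or PredictorState.

    The file embeds a JSON header with layer dimensions, provenance/task
    and training history; weight values round-trip bit-identically.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        if isinstance(state, EncoderState):
            header = {
                "kind": "encoder",
                "spec": _spec_header(state.spec),
                "provenance": state.provenance,
                "selected_genes": state.selected_genes,
                "history": state.history,
            }
            _write_layers(f.create_group("encoder"), state.layers)
        elif isinstance(state, AutoencoderWeights):
            header = {"kind": "autoencoder", "spec": _spec_header(state.spec), "history": state.history}
            _write_layers(f.create_group("encoder"), state.encoder_layers)
            _write_layers(f.create_group("decoder"), state.decoder_layers)
        elif isinstance(state, PredictorState):
            header = {
                "kind": "predictor",
                "spec": _spec_header(state.encoder.spec),
                "provenance": state.encoder.provenance,
                "selected_genes": state.encoder.selected_genes,
                "head_dims": state.head_dims,
                "task": state.task,
                "alpha": state.alpha,
                "history": state.history,
                "encoder_history": state.encoder.history,
            }
            _write_layers(f.create_group("encoder"), state.encoder.layers)
            _write_layers(f.create_group("head"), state.head_layers)
        else:
            raise TypeError(f"cannot save object of type {type(state).__name__}")
        f.attrs["header"] = json.dumps(header)


def load_weights(path, expected_spec: AutoencoderSpec | None = None):
    """Load a weight file saved by :func:`save_weights`.

    With ``expected_spec`` given, layer dimensions in the file must match
    it exactly or a ValueError is raised.
    """
    with h5py.File(path, "r") as f:
        header = json.loads(f.attrs["header"])
        spec = AutoencoderSpec(**header["spec"])
        if expected_spec is not None and spec != expected_spec:
            raise ValueError(
                f"weight file spec {header['spec']} does not match the declared "
                f"spec {_spec_header(expected_spec)}"
            )
        kind = header["kind"]
        if kind == "encoder":
            return EncoderState(
                spec=spec,
                layers=_read_layers(f["encoder"]),
                provenance=header["provenance"],
                selected_genes=header.get("selected_genes"),
                history=header.get("history", []),
            )
        if kind == "autoencoder":
            return AutoencoderWeights(
                spec=spec,
                encoder_layers=_read_layers(f["encoder"]),
                decoder_layers=_read_layers(f["decoder"]),
                history=header.get("history", []),
            )
        if kind == "predictor":
            encoder = EncoderState(
                spec=spec,
                layers=_read_layers(f["encoder"]),
                provenance=header["provenance"],
                selected_genes=header.get("selected_genes"),
                history=header.get("encoder_history", []),
            )
            return PredictorState(
                encoder=encoder,
                head_layers=_read_layers(f["head"]),
                head_dims=header["head_dims"],
                task=header["task"],
                alpha=header.get("alpha", 0.1),
                history=header.get("history", []),
            )
        raise ValueError(f"unknown weight-file kind {kind!r}")
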