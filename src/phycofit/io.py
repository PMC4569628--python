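"""Reading and writing datasets (CSV) and fit results (JSON).

One fixed CSV dialect is used everywhere: comma-separated, UTF-8,
header required, ``.`` decimal; columns ``time``, ``biomass`` and
(optionally) ``product``.  Numbers are serialized with ``repr``
precision (17 significant digits) so values round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import TimeSeriesDataset
from .diagnostics import GadenClass
from .estimators import FitResult
from .kinetics import LogisticParams, LuedekingPiretParams

__all__ = [
    "read_dataset",
    "write_dataset",
    "result_record",
    "write_results",
    "read_results",
    "file_checksum",
]

try:
    _VERSION = version("phycofit")
except PackageNotFoundError:  # pragma: no cover - only outside an install
    _VERSION = "unknown"


def read_dataset(
    path: str | Path,
    condition_label: str = "",
    time_unit: str = "h",
    provenance: str = "observed",
) -> TimeSeriesDataset:
    """Read a dataset CSV (columns ``time``, ``biomass``, optional ``product``).

    Malformed files are rejected with the offending column or row named:
    missing columns, non-numeric cells, and non-increasing times all
    raise ``ValueError``.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time", "biomass"} - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {sorted(missing)}")
    for col in ("time", "biomass", "product"):
        if col not in df.columns:
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if df[col].isna().any() or len(bad):
            rows = list((df.index[df[col].isna()].tolist() + bad.tolist()))
            raise ValueError(
                f"{path.name}: non-numeric or missing value(s) in column "
                f"'{col}' at data row(s) {sorted(set(int(r) + 2 for r in rows))} "
                "(1-based, counting the header)"
            )
        df[col] = numeric
    t = df["time"].to_numpy(dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3  # 1-based incl. header
        raise ValueError(f"{path.name}: time not strictly increasing at row {row}")
    return TimeSeriesDataset(
        times=t,
        biomass=df["biomass"].to_numpy(dtype=float),
        product=df["product"].to_numpy(dtype=float) if "product" in df.columns else None,
        condition_label=condition_label,
        time_unit=time_unit,
        provenance=provenance,
    )


def write_dataset(data: TimeSeriesDataset, path: str | Path) -> None:
    """Write a dataset to CSV with full float precision.

    For synthetic datasets carrying a generating config, a JSON sidecar
    ``<path>.config.json`` records the configuration.
    """
    path = Path(path)
    cols = {"time": data.times, "biomass": data.biomass}
    if data.has_product:
        cols["product"] = data.product
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    if data.config is not None:
        sidecar = path.with_suffix(path.suffix + ".config.json")
        cfg = data.config
        record = {
            "condition_label": cfg.condition_label,
            "growth": {"x0": cfg.growth.x0, "k": cfg.growth.k, "xs": cfg.growth.xs},
            "prod": {
                "alpha": cfg.prod.alpha,
                "beta": cfg.prod.beta,
                "p0": cfg.prod.p0,
            },
            "times": None if cfg.times is None else list(map(float, cfg.times)),
            "n_points": cfg.n_points,
            "t_span": list(cfg.t_span),
            "noise_sd_biomass": cfg.noise_sd_biomass,
            "noise_sd_product": cfg.noise_sd_product,
            "seed": cfg.seed,
        }
        sidecar.write_text(json.dumps(record, indent=1) + "\n", encoding="utf-8")


def file_checksum(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def result_record(result: FitResult, input_checksum: str | None = None) -> dict:
    """A fit result as a plain dict with a stable key order."""
    return {
        "condition_label": result.condition_label,
        "growth": {
            "x0": result.growth.x0,
            "k": result.growth.k,
            "xs": result.growth.xs,
        },
        "prod": {
            "alpha": result.prod.alpha,
            "beta": result.prod.beta,
            "p0": result.prod.p0,
        },
        "r2_growth": result.r2_growth,
        "r2_product": result.r2_product,
        "pct_error_growth": result.pct_error_growth,
        "pct_error_product": result.pct_error_product,
        "gaden_class": str(result.gaden_class),
        "tool_version": _VERSION,
        "input_checksum": input_checksum,
    }


def write_results(
    result: FitResult, path: str | Path, input_checksum: str | None = None
) -> None:
    """Serialize a fit result to JSON with a stable key order.

    Includes all estimated parameters, diagnostics, the Gaden class (as
    its roman numeral), the tool version, and optionally a checksum of
    the input file, so two runs on the same input produce identical
    files.
    """
    record = result_record(result, input_checksum)
    Path(path).write_text(json.dumps(record, indent=1) + "\n", encoding="utf-8")


def read_results(path: str | Path) -> FitResult:
    """Read a fit-result JSON written by :func:`write_results`."""
    record = json.loads(Path(path).read_text(encoding="utf-8"))
    return FitResult(
        growth=LogisticParams(**record["growth"]),
        prod=LuedekingPiretParams(**record["prod"]),
        r2_growth=record["r2_growth"],
        r2_product=record["r2_product"],
        pct_error_growth=record["pct_error_growth"],
        pct_error_product=record["pct_error_product"],
        gaden_class=GadenClass(record["gaden_class"]),
        condition_label=record["condition_label"],
    )
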