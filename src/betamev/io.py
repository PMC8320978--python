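"""Dataset reading, run configuration and result writing."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .estimation import FitResult
from .forms import make_form
from .measurement_error import (MeasurementErrorConfig, calibration_regression,
                                pooled_replicate_variance)
from .model import Dataset, ModelSpec

log = logging.getLogger("betamev")


def _read_table(path: str) -> pd.DataFrame:
    """Delimited text with a header row; comma default, tab accepted."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") > first.count(",") else ","
    return pd.read_csv(path, sep=sep)


def read_dataset(path: str, response: str = "y",
                 columns: Optional[Sequence[str]] = None) -> Dataset:
    """Load a delimited dataset, validating the used columns.

    Rows with missing values in used columns are rejected with their row
    indices; the response must lie strictly inside (0, 1); unused extra
    columns are kept (and logged).
    """
    frame = _read_table(path)
    used = [response] + [c for c in (columns or frame.columns) if c != response]
    missing_cols = [c for c in used if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {missing_cols}")
    extra = [c for c in frame.columns if c not in used]
    if extra:
        log.info("%s: ignoring unused column(s) %s", path, extra)
    sub = frame[used]
    bad = sub.isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"{path}: missing values in used columns at row(s) "
            f"{list(np.flatnonzero(bad.to_numpy()))}"
        )
    y = sub[response].to_numpy(dtype=float)
    out_of_range = (y <= 0.0) | (y >= 1.0)
    if out_of_range.any():
        raise ValueError(
            f"{path}: response outside the open interval (0, 1) at row(s) "
            f"{list(np.flatnonzero(out_of_range))}"
        )
    cols = {c: sub[c].to_numpy(dtype=float) for c in used if c != response}
    return Dataset(y, cols)


@dataclass
class RunConfig:
    """Parsed run configuration (model + measurement error + estimation)."""

    spec: ModelSpec
    me_config: Optional[MeasurementErrorConfig]
    methods: List[str] = field(default_factory=lambda: ["pml"])
    Q: int = 50
    levels: Tuple[float, ...] = (0.95,)
    seed: int = 0
    replicate_columns: Optional[List[str]] = None


def load_run_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    model = raw.get("model", {})
    cols = raw.get("columns", {})

    def build_form(section, default_link):
        form = make_form(section.get("form", "linear"),
                         section.get("covariates", []))
        return form, section.get("link", default_link), bool(
            section.get("uses_error_prone", False))

    mean_form, mean_link, mean_x = build_form(model.get("mean", {}), "logit")
    prec_form, prec_link, prec_x = build_form(model.get("precision", {}), "log")
    spec = ModelSpec(mean_form, prec_form, mean_link=mean_link,
                     precision_link=prec_link, mean_has_x=mean_x,
                     precision_has_x=prec_x,
                     response=cols.get("response", "y"),
                     error_prone=cols.get("error_prone", "w"))

    me_raw = raw.get("measurement_error", {}) or {}
    sources = [k for k in ("sigma_e2", "calibration", "replicates") if k in me_raw]
    if len(sources) > 1:
        raise ValueError("exactly one sigma_e2 source may be given "
                         f"(found {sources})")
    me_config = None
    replicate_columns = None
    if "sigma_e2" in me_raw:
        me_config = MeasurementErrorConfig(sigma_e2=float(me_raw["sigma_e2"]),
                                           tau1=float(me_raw.get("tau1", 0.0)),
                                           tau2=float(me_raw.get("tau2", 1.0)))
    elif "calibration" in me_raw:
        pairs = _read_table(me_raw["calibration"])
        cal = calibration_regression(pairs.iloc[:, 0], pairs.iloc[:, 1])
        log.info("calibration: tau1=%.4g (%.4g) tau2=%.4g (%.4g) "
                 "sigma_e2=%.5g R2=%.3f", cal.tau1, cal.se_tau1, cal.tau2,
                 cal.se_tau2, cal.sigma_e2, cal.r2)
        me_config = MeasurementErrorConfig(sigma_e2=cal.sigma_e2,
                                           tau1=cal.tau1, tau2=cal.tau2)
    elif "replicates" in me_raw:
        replicate_columns = list(me_raw["replicates"])

    est = raw.get("estimation", {}) or {}
    return RunConfig(spec=spec, me_config=me_config,
                     methods=list(est.get("methods", ["pml"])),
                     Q=int(est.get("Q", 50)),
                     levels=tuple(est.get("levels", [0.95])),
                     seed=int(est.get("seed", 0)),
                     replicate_columns=replicate_columns)


def resolve_replicate_sigma(config: RunConfig, frame_path: str) -> RunConfig:
    """Fill sigma_e2 from replicate columns of the data file, and replace the
    error-prone column by the replicate mean convention (first column)."""
    if config.replicate_columns is None:
        return config
    frame = _read_table(frame_path)
    W = frame[config.replicate_columns].to_numpy(dtype=float)
    sigma_e2 = pooled_replicate_variance(W)
    config.me_config = MeasurementErrorConfig(sigma_e2=sigma_e2)
    log.info("replicate columns %s -> pooled sigma_e2=%.5g",
             config.replicate_columns, sigma_e2)
    return config


def write_fit_results(results: Dict[str, FitResult], outdir: str,
                      levels: Sequence[float]) -> List[str]:
    """One text report per method plus a combined machine-readable table."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    rows = []
    for method, res in results.items():
        p = os.path.join(outdir, f"fit_{method}.txt")
        with open(p, "w") as fh:
            fh.write(res.summary(levels) + "\n")
        paths.append(p)
        tab = res.to_frame(levels)
        tab.insert(0, "parameter", tab.index)
        tab.insert(0, "method", method)
        tab["converged"] = res.converged
        tab["loglik"] = res.loglik
        tab["Q"] = res.Q if res.Q is not None else ""
        rows.append(tab)
    combined = os.path.join(outdir, "fit_results.csv")
    pd.concat(rows, ignore_index=True).to_csv(combined, index=False,
                                              float_format="%.6g")
    paths.append(combined)
    return paths
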