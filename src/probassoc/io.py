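"""Readers, writers, run configuration and the end-to-end pipeline.

The pipeline ties the stages together: empirical LIR -> residence-model fit
-> probabilistic association threshold -> per-day associations under one or
more criteria -> half-weight matrices -> the evaluation battery (CVs with
permutation P values, Mantel test against a membership attribute, modularity
clustering, social differentiation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .associations import (CRITERIA, daily_associations, hwi_matrix,
                           restrict_individuals)
from .lir import ResidenceTimeModel
from .metrics import (mantel_test, newman_clusters, permute_within_days,
                      social_differentiation)
from .records import REQUIRED_COLUMNS

__all__ = ["read_identifications", "write_identifications", "RunConfig",
           "run_pipeline", "export_graphml"]


def read_identifications(path, column_map: Mapping[str, str] | None = None
                         ) -> pd.DataFrame:
    """Read an identification-record CSV into the canonical frame.

    ``column_map`` maps canonical names (individual, event, ordinal, date) to
    the file's column names.  Dates must parse as ISO-8601; rows failing to
    parse are reported with their line numbers.  Exact duplicate rows are
    dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no records")
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in REQUIRED_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} "
                         f"(available: {list(df.columns)})")
    df = df.rename(columns=rename)

    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = df.index[parsed.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]  # header is line 1
        raise ValueError(f"{path}: unparseable date(s) at line(s) {lines}"
                         + (" ..." if len(bad) > 5 else ""))
    df["date"] = parsed.dt.date
    df["ordinal"] = pd.to_numeric(df["ordinal"], errors="raise")

    n0 = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    if len(df) < n0:
        warnings.warn(f"{path}: dropped {n0 - len(df)} duplicate rows")
    return df


def write_identifications(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = out["date"].astype(str)
    out.to_csv(path, index=False)


def export_graphml(matrix, path) -> None:
    """Write the weighted association network as GraphML."""
    import networkx as nx

    nx.write_graphml(matrix.to_graph(), path)


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one threshold source applies: ``threshold`` set to an integer
    uses it directly; left as None, the threshold is fitted from the data.
    """

    input: str | None = None
    column_map: dict = field(default_factory=dict)
    criteria: Sequence[str] = ("probabilistic", "same_frame", "encounter")
    threshold: int | None = None
    max_lag: float | str = "auto"
    min_days: int = 5
    require_years: Sequence[int] = ()
    membership_attr: str | None = None
    subset_attr: str | None = None
    n_permutations: int = 1000
    n_trials: int = 1000
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _matrix_summary(matrix) -> dict:
    vals = matrix.offdiag()
    nz = vals[vals > 0]
    out = {
        "n_individuals": len(matrix.individuals),
        "n_dyads": int(len(vals)),
        "mean_hwi": float(vals.mean()),
        "sd_hwi": float(vals.std(ddof=0)),
        "nonzero_mean_hwi": float(nz.mean()) if len(nz) else 0.0,
        "nonzero_sd_hwi": float(nz.std(ddof=0)) if len(nz) else 0.0,
        "pct_zero": float(100.0 * np.mean(vals == 0)),
        "pct_nonzero_below_half": float(100.0 * np.mean((vals > 0) & (vals < 0.5))),
        "pct_at_least_half": float(100.0 * np.mean(vals >= 0.5)),
    }
    return out


def run_pipeline(config: RunConfig, records: pd.DataFrame | None = None) -> dict:
    """Execute the full analysis and return the evaluation report.

    ``records`` may be passed directly (e.g. a simulated stream); otherwise
    ``config.input`` is read.  When ``config.outdir`` is set, the fit JSON,
    LIR curve CSV, HWI matrices, edge lists, GraphML networks and the report
    JSON are written there.  Deterministic given the seed.
    """
    if records is None:
        if config.input is None:
            raise ValueError("either records or config.input is required")
        records = read_identifications(config.input, config.column_map)
    for crit in config.criteria:
        if crit not in CRITERIA:
            raise ValueError(f"unknown criterion {crit!r}")

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"software_version": __version__, "seed": config.seed,
                    "config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(config).items()}}

    # --- stage 1: association threshold --------------------------------
    if config.threshold is not None:
        threshold = int(config.threshold)
        report["threshold"] = {"source": "explicit", "threshold": threshold}
    else:
        model = ResidenceTimeModel.from_records(records, max_lag=config.max_lag)
        fit = model.fit(seed=config.seed)
        if fit.threshold is None:
            raise RuntimeError(
                "stage lir: residence-model fit did not yield a threshold "
                "(non-convergent or non-informative); supply --threshold")
        threshold = fit.threshold.threshold
        report["threshold"] = {"source": "fitted", **fit.to_dict()}
        if outdir:
            fit.to_json(outdir / "residence_fit.json")
            model.curve.to_csv(outdir / "lir_curve.csv")

    # --- stage 2: individual restriction --------------------------------
    ids = restrict_individuals(records, min_days=config.min_days,
                               require_periods=config.require_years)
    if not ids:
        raise RuntimeError("stage filter: no individuals satisfy the "
                           "restriction; relax min_days/require_years")
    report["n_individuals_retained"] = len(ids)

    membership = None
    if config.membership_attr:
        if config.membership_attr not in records.columns:
            raise ValueError(f"membership attribute {config.membership_attr!r} "
                             "not in records")
        membership = (records.drop_duplicates("individual")
                      .set_index("individual")[config.membership_attr]
                      .to_dict())

    # --- stage 3 + 4: associations and evaluation per criterion ---------
    report["criteria"] = {}
    for crit in config.criteria:
        assoc = daily_associations(
            records, crit,
            threshold=threshold if crit == "probabilistic" else None,
            ids=ids)
        matrix = hwi_matrix(assoc, ids=ids)
        entry = {"criterion": crit, "association_index": _matrix_summary(matrix)}

        cv = permute_within_days(assoc, ids=sorted(ids),
                                 n_permutations=config.n_permutations,
                                 n_trials=config.n_trials, seed=config.seed)
        entry["cv"] = {"cv_hwi": cv.cv_all, "p_value": cv.p_all,
                       "cv_nonzero_hwi": cv.cv_nonzero,
                       "p_value_nonzero": cv.p_nonzero,
                       "n_permutations": cv.n_permutations,
                       "n_trials": cv.n_trials}
        if membership is not None:
            mt = mantel_test(matrix, membership,
                             n_permutations=config.n_permutations,
                             seed=config.seed)
            entry["mantel"] = {"matrix_correlation": mt.matrix_correlation,
                               "p_value": mt.p_value}
        part = newman_clusters(matrix)
        entry["modularity"] = {"q": part.q, "n_clusters": part.n_clusters,
                               "cluster_sizes": part.cluster_sizes}
        sd = social_differentiation(assoc, ids=sorted(ids))
        entry["social_differentiation"] = {"s": sd.s, "loglik": sd.loglik,
                                           "boundary": sd.boundary}
        report["criteria"][crit] = entry

        if outdir:
            matrix.to_csv(outdir / f"hwi_{crit}.csv")
            matrix.edge_list().to_csv(outdir / f"edges_{crit}.csv", index=False)
            export_graphml(matrix, outdir / f"network_{crit}.graphml")
            pd.DataFrame(
                [{"individual": i, "cluster": part.assignment[i]}
                 for i in matrix.individuals]
            ).to_csv(outdir / f"clusters_{crit}.csv", index=False)

    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True,
                      default=_json_default)
    return report


def _json_default(obj):
    """Coerce numpy scalars left in report entries."""
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
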