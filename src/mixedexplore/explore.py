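"""Sweep every candidate model over one dataset and rank the results.

``explore_models`` fits the full enumerated candidate list on a common
listwise-complete row set and returns an :class:`ExplorationTable` with one
row per candidate (rendered formula, log-likelihood, AIC, BIC, parameter
count, convergence and singularity flags) in enumeration order.

Work is partitioned by candidate index and reassembled in enumeration
order, so the table is bit-identical for any worker count: parallelism is
an implementation detail, never a semantics change.  Failed fits are
flagged and kept — an exhaustive sweep is exploratory by design and must
not abort on one bad candidate.

``sort_result`` ranks ascending by AIC or BIC or descending by LL, placing
failed (NaN-criterion) fits last; ties break by fewer parameters, then by
the canonical formula string.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .candidates import CandidateSet, enumerate_candidates
from .fit import FitError, FitResult, OptimizerSettings, fit_model, listwise_complete
from .formula import ModelFormula

__all__ = [
    "ExplorationTable",
    "best_models",
    "explore_models",
    "read_results",
    "sort_result",
    "write_results",
]

CRITERIA = ("BIC", "AIC", "LL")

_COLUMNS = ["formula", "stratum", "logLik", "AIC", "BIC",
            "n_params", "converged", "singular"]


@dataclass
class ExplorationTable:
    """Per-candidate fit summaries plus run metadata."""

    rows: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)


def _fit_one(m: ModelFormula, data: pd.DataFrame, opts: OptimizerSettings) -> dict:
    try:
        r: FitResult = fit_model(m, data, opts)
        return {
            "formula": m.render(), "logLik": r.loglik, "AIC": r.aic,
            "BIC": r.bic, "n_params": r.n_params, "converged": r.converged,
            "singular": r.singular,
        }
    except FitError as exc:
        return {
            "formula": m.render(), "logLik": float("nan"), "AIC": float("nan"),
            "BIC": float("nan"), "n_params": 0, "converged": False,
            "singular": False, "error": str(exc),
        }


def explore_models(
    data: pd.DataFrame,
    full: ModelFormula,
    workers: int = 1,
    opts: OptimizerSettings | None = None,
    ceiling_force: bool = False,
) -> ExplorationTable:
    """Fit every candidate implied by ``full`` and tabulate LL/AIC/BIC.

    ``workers`` sets the joblib process count (1 means in-process serial);
    the result is identical for any value.  Rows with missingness in any
    column of the full model are dropped once, up front, so all candidates
    share the same N.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    opts = opts or OptimizerSettings()
    cs: CandidateSet = enumerate_candidates(full, force=ceiling_force)
    used = listwise_complete(data, full)
    if full.group is not None and used[full.group].nunique() < 2:
        raise FitError(
            f"group column {full.group!r} has a single level; "
            "random effects need at least two groups"
        )
    t0 = time.perf_counter()
    if workers == 1:
        records = [_fit_one(m, used, opts) for m in cs]
    else:
        records = Parallel(n_jobs=workers, batch_size="auto")(
            delayed(_fit_one)(m, used, opts) for m in cs
        )
    elapsed = time.perf_counter() - t0
    rows = pd.DataFrame(records)
    rows.insert(1, "stratum", list(cs.strata))
    failures = int((~rows["converged"]).sum())
    meta = {
        "full_model": full.render(),
        "forced": list(full.forced),
        "slope_candidates": list(full.random_slopes),
        "n_obs": int(len(used)),
        "n_groups": int(used[full.group].nunique()) if full.group else 0,
        "n_candidates": len(cs),
        "workers": workers,
        "elapsed_seconds": elapsed,
        "n_not_converged": failures,
        "version": __version__,
    }
    return ExplorationTable(rows[_COLUMNS + [c for c in rows.columns
                                             if c not in _COLUMNS]], meta)


def sort_result(t: ExplorationTable, criterion: str = "BIC") -> ExplorationTable:
    """Rank candidates by an information criterion (default BIC).

    AIC/BIC sort ascending (lower is better), LL descending.  Rows whose
    criterion is missing (failed fits) go last; ties break by fewer
    parameters then by formula string, so the ordering is total and stable.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")
    if len(t) == 0:
        raise ValueError("cannot sort an empty exploration table")
    col = "logLik" if criterion == "LL" else criterion
    rows = t.rows.copy()
    key = rows[col] if criterion != "LL" else -rows[col]
    rows = (
        rows.assign(_key=key)
        .sort_values(["_key", "n_params", "formula"], kind="mergesort",
                     na_position="last")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    meta = dict(t.meta, sorted_by=criterion)
    return ExplorationTable(rows, meta)


def best_models(
    t: ExplorationTable, k: int = 1, criterion: str = "BIC"
) -> pd.DataFrame:
    """First ``k`` rows of the ranked table (``k`` capped at table size)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sort_result(t, criterion).rows.head(k).reset_index(drop=True)


def write_results(t: ExplorationTable, csv_path: str | Path,
                  meta_path: str | Path | None = None) -> None:
    """Write the table as CSV (criteria at 6 decimals) plus a JSON sidecar."""
    csv_path = Path(csv_path)
    t.rows.to_csv(csv_path, index=False, float_format="%.6f")
    if meta_path is None:
        meta_path = csv_path.with_suffix(".meta.json")
    Path(meta_path).write_text(json.dumps(t.meta, indent=2) + "\n")


def read_results(csv_path: str | Path,
                 meta_path: str | Path | None = None) -> ExplorationTable:
    """Round-trip reader for :func:`write_results` output."""
    csv_path = Path(csv_path)
    rows = pd.read_csv(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".meta.json")
    meta = {}
    mp = Path(meta_path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    return ExplorationTable(rows, meta)
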