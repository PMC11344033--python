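"""Tabular report writing for cohort analyses."""

from __future__ import annotations

import dataclasses
import json
import os

import pandas as pd

from . import __version__
from .errors import ErrorSummary, RegressionResult

__all__ = ["run_report"]


def run_report(
    records: pd.DataFrame,
    summaries: dict[str, ErrorSummary],
    regressions: dict[str, RegressionResult],
    out_dir: str | os.PathLike,
    seed: int | None = None,
    config_hash: str | None = None,
) -> dict:
    """Write cohort records, error summaries and regressions to disk.

    Emits ``records.csv``, ``summaries.csv``, ``regressions.csv`` and a
    combined ``report.json`` (which also records the software version,
    seed and configuration hash). Percentages carry a ``_pct`` suffix in
    the column names. Returns the JSON payload.
    """
    if records is None or len(records) == 0:
        raise ValueError("no records")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    records.to_csv(os.path.join(out_dir, "records.csv"), index=False)

    sum_rows = [
        {"label": k, **dataclasses.asdict(v)} for k, v in summaries.items()
    ]
    reg_rows = [
        {"label": k, **dataclasses.asdict(v)} for k, v in regressions.items()
    ]
    pd.DataFrame(sum_rows).to_csv(os.path.join(out_dir, "summaries.csv"), index=False)
    pd.DataFrame(reg_rows).to_csv(os.path.join(out_dir, "regressions.csv"), index=False)

    payload = {
        "software": {"name": "qctcal", "version": __version__},
        "seed": seed,
        "config_hash": config_hash,
        "n_records": int(len(records)),
        "summaries": {k: dataclasses.asdict(v) for k, v in summaries.items()},
        "regressions": {k: dataclasses.asdict(v) for k, v in regressions.items()},
    }
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return payload
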