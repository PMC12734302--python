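"""Readers and writers for the package's tabular formats.

The canonical on-disk format for an empirical offspring PMF is a
two-column TSV with header ``k<TAB>prob``, rows sorted by k; counts absent
from the file have probability 0.  Results are written as TSV (mirroring
the layouts a reader would tabulate by hand) or as JSON carrying the same
content; floats are rendered at 10 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .laws import EmpiricalLaw

__all__ = ["read_pmf_table", "write_pmf_table", "write_report", "result_frame"]

_FLOAT_FMT = "%.10g"


def read_pmf_table(path) -> EmpiricalLaw:
    """Read an empirical offspring law from a two-column TSV.

    Expects header ``k`` and ``prob``; missing counts are implicitly 0,
    duplicate counts are rejected, and the probability column must be a
    valid PMF (sum-to-one policy as in :class:`EmpiricalLaw`).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["k", "prob"]:
        raise ValueError(
            f"{path}: expected header 'k<TAB>prob', found {list(df.columns)!r}"
        )
    if df["k"].duplicated().any():
        dupes = sorted(df.loc[df["k"].duplicated(), "k"].unique().tolist())
        raise ValueError(f"{path}: duplicate offspring counts {dupes}")
    k = df["k"].to_numpy()
    if not np.issubdtype(k.dtype, np.integer) or (k < 0).any():
        raise ValueError(f"{path}: offspring counts must be nonnegative integers")
    prob = df["prob"].to_numpy(dtype=float)
    if np.any(prob < 0):
        raise ValueError(f"{path}: negative probabilities are not allowed")
    dense = np.zeros(int(k.max()) + 1)
    dense[k] = prob
    return EmpiricalLaw(dense)


def write_pmf_table(law: EmpiricalLaw, path) -> None:
    """Write an empirical law in the canonical two-column TSV format."""
    df = pd.DataFrame({"k": np.arange(law.probs.size), "prob": law.probs})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def result_frame(result) -> pd.DataFrame:
    """Tabular view of any result object from the analytic modules.

    Distribution-like results (extinction-time, size distributions) become
    one row per generation/size; scalar summaries become a single-row
    frame with deterministic column order.
    """
    from .extinction_time import ExtinctionTimeDist
    from .sizedist import SizeDistribution

    if isinstance(result, ExtinctionTimeDist):
        t = np.arange(result.q.size)
        one_minus = 1.0 - result.q
        return pd.DataFrame(
            {
                "t": t,
                "q_t": result.q,
                "pmf": np.concatenate([[np.nan], result.pmf]),
                "1-q_t": one_minus,
                "(2t+1)(1-q_t)": (2 * t + 1) * one_minus,
            }
        )
    if isinstance(result, SizeDistribution):
        return pd.DataFrame(
            {"m": np.arange(result.probs.size), "prob": result.probs}
        )
    if dataclasses.is_dataclass(result):
        row = {
            f.name: getattr(result, f.name)
            for f in dataclasses.fields(result)
            if np.isscalar(getattr(result, f.name))
            or getattr(result, f.name) is None
        }
        return pd.DataFrame([row])
    if isinstance(result, dict):
        return pd.DataFrame([result])
    raise TypeError(f"cannot tabulate result of type {type(result).__name__}")


def write_report(result, path, fmt: str = "tsv") -> None:
    """Write a result as TSV or as JSON mirroring the TSV content."""
    df = result_frame(result)
    path = Path(path)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    elif fmt == "json":
        records = json.loads(df.to_json(orient="records"))
        path.write_text(json.dumps(records, indent=1) + "\n")
    else:
        raise ValueError(f"unknown output format {fmt!r}")
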