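"""Benchmark harness: timing, evaluation metrics and statistical comparisons.

Per dataset and codec the harness reports six metrics:

* CT / DCT — compression / decompression wall time (milliseconds), the
  median over a configurable number of repetitions (default 5) after one
  discarded warm-up run, measured with the monotonic high-resolution
  timer ``time.perf_counter_ns``.
* CR / DCR — compression / decompression rate (megabytes per second,
  1 MB = 10**6 bytes): the uncompressed byte size divided by CT / DCT.
* CM — compressed memory: the byte length of the serialized container
  (the on-disk measure; the in-memory array total is reported alongside).
* CRO — compression ratio: uncompressed bytes / CM (dimensionless, > 1
  means the container is smaller than the dense array).

The uncompressed size is the dense array's in-memory footprint at the
value precision the container stores.  Before any timing is accepted the
harness verifies that decompression reproduces the input cell-for-cell;
a mismatch aborts that dataset x codec cell with an integrity error, so
timings are never reported for a lossy run.

Statistical comparisons mirror the benchmark study design: paired-sample
t-tests between codecs on a common set of datasets, Spearman rank
correlation (tie-aware, t-approximation p-values) between each metric and
each dataset characteristic, and mean +/- sample SD summaries.
"""

from __future__ import annotations

import statistics
import time
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateDataError, IntegrityError
from .matrixio import MutationMatrix, profile_dataset
from .pipeline import CODECS, compress, decompress, serialize_bytes

__all__ = [
    "BenchmarkRecord",
    "measure",
    "run_benchmark",
    "records_frame",
    "paired_t_test",
    "spearman",
    "summarize",
    "correlation_table",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("ct_ms", "dct_ms", "cr_mb_s", "dcr_mb_s", "cm_bytes", "cro")

_TIMER = time.perf_counter_ns


@dataclass
class BenchmarkRecord:
    """Metrics for one dataset x codec cell."""

    dataset: str
    codec: str
    ct_ms: float
    dct_ms: float
    cr_mb_s: float
    dcr_mb_s: float
    cm_bytes: int
    cm_array_bytes: int
    cro: float
    pre_bytes: int
    repetitions: int
    timer: str = "time.perf_counter_ns"


def _median_ms(fn, repetitions: int) -> float:
    times = []
    for _ in range(repetitions + 1):  # first run is a discarded warm-up
        t0 = _TIMER()
        fn()
        times.append((_TIMER() - t0) / 1e6)
    return statistics.median(times[1:])


def measure(M: MutationMatrix, codec: str, repetitions: int = 5,
            dataset: str = "dataset") -> BenchmarkRecord:
    """Time one dataset under one codec; verifies losslessness first."""
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    container = compress(M, codec, include_labels=False)
    restored = decompress(container)
    if not restored.equals(M, check_labels=False):
        raise IntegrityError(
            f"codec {codec!r} failed the lossless round-trip on {dataset!r}; "
            "timings withheld"
        )
    pre_bytes = M.m * M.n * container.value_dtype.itemsize
    blob = serialize_bytes(container)
    ct_ms = _median_ms(lambda: compress(M, codec, include_labels=False), repetitions)
    dct_ms = _median_ms(lambda: decompress(container), repetitions)
    return BenchmarkRecord(
        dataset=dataset,
        codec=codec,
        ct_ms=ct_ms,
        dct_ms=dct_ms,
        cr_mb_s=(pre_bytes / 1e6) / (ct_ms / 1e3),
        dcr_mb_s=(pre_bytes / 1e6) / (dct_ms / 1e3),
        cm_bytes=len(blob),
        cm_array_bytes=container.array_bytes(),
        cro=pre_bytes / len(blob),
        pre_bytes=pre_bytes,
        repetitions=repetitions,
    )


def run_benchmark(datasets, codecs=CODECS, repetitions: int = 5) -> list[BenchmarkRecord]:
    """Benchmark every dataset x codec cell.

    ``datasets`` is an iterable of ``(name, MutationMatrix)`` pairs (bare
    matrices are accepted and auto-named ``d0``, ``d1``, ...).
    """
    records = []
    for k, item in enumerate(datasets):
        if isinstance(item, MutationMatrix):
            name, M = f"d{k}", item
        else:
            name, M = item
        for codec in codecs:
            records.append(measure(M, codec, repetitions=repetitions, dataset=name))
    return records


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def paired_t_test(x, y) -> tuple[float, float]:
    """Paired-sample t-test: t = mean(d) / (sd(d)/sqrt(n)) on d = x - y.

    Two-sided p from Student's t with n-1 degrees of freedom.  Constant
    differences (zero variance) are a degenerate input, flagged as an
    error rather than returned as NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("differences have zero variance; t is undefined")
    t = float(d.mean()) / (sd / np.sqrt(n))
    p = 2.0 * float(scipy.stats.t.sf(abs(t), n - 1))
    return t, p


def spearman(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation with t-approximation p-value.

    rho is the Pearson correlation of average-assigned ranks; the two-sided
    p comes from t = rho * sqrt((n-2) / (1-rho**2)) with n-2 degrees of
    freedom.  Constant inputs have no defined rank correlation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs at least three observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("constant vector: rank correlation undefined")
    rx = scipy.stats.rankdata(x, method="average")
    ry = scipy.stats.rankdata(y, method="average")
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.clip(np.mean(rx * ry), -1.0, 1.0))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(scipy.stats.t.sf(abs(t), n - 2))
    return rho, p


def summarize(frame: pd.DataFrame, by, cols) -> pd.DataFrame:
    """Mean +/- sample SD (ddof=1) per group; groups with < 2 rows are skipped."""
    if isinstance(by, str):
        by = [by]
    rows = []
    for keys, grp in frame.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        if len(grp) < 2:
            continue
        for col in cols:
            v = grp[col].to_numpy(dtype=np.float64)
            rows.append(dict(zip(by, keys)) | {
                "metric": col,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)),
                "n": len(v),
            })
    return pd.DataFrame(rows)


def correlation_table(metric_frame: pd.DataFrame, profile_frame: pd.DataFrame,
                      metric_cols=METRIC_COLUMNS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho (and p) of each metric against each dataset characteristic.

    ``metric_frame`` must carry one row per dataset (a single codec's
    records, or pre-filtered) keyed by ``dataset``; ``profile_frame`` one
    characteristics row per dataset, also keyed by ``dataset``.
    Returns ``(rho, p)`` DataFrames indexed by metric.
    """
    merged = metric_frame.merge(profile_frame, on="dataset", suffixes=("", "_prof"))
    char_cols = [c for c in profile_frame.columns if c != "dataset"]
    rho = pd.DataFrame(index=list(metric_cols), columns=char_cols, dtype=float)
    pval = pd.DataFrame(index=list(metric_cols), columns=char_cols, dtype=float)
    for mc in metric_cols:
        for cc in char_cols:
            if len(merged) < 3:
                r, p = np.nan, np.nan  # too few datasets for a rank correlation
            else:
                try:
                    r, p = spearman(merged[mc], merged[cc])
                except DegenerateDataError:
                    r, p = np.nan, np.nan
            rho.loc[mc, cc] = r
            pval.loc[mc, cc] = p
    return rho, pval
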