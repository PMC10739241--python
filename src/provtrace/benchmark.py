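"""Runtime-scaling experiment for the capture path.

For each block size a fresh store is populated element by element and the
wall time is split into the per-element capture cost (the ``record`` loop
alone) and the per-record cost (including store creation, session
dimension writes and commits), together with database file growth.
Absolute timings are hardware-bound; the property of interest is that the
log-log slope of total insert time versus block size is near 1 — capture
cost scales nearly linearly with input size.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from itertools import islice
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fixtures import DEMO_OWNER, DEMO_POLICY, DEMO_SCRIPT, DEMO_STEWARD, builtin_element_types, generate_elements
from .store import ProvenanceStore

#: Block sizes of the reference experiment design (1..100,000 decades; the
#: full design extends to 9, 90, ..., 900,000 on dedicated machines).
DEFAULT_BLOCKS = (1, 10, 100, 1000, 10000)


@dataclass(frozen=True)
class TimingRow:
    """Timing and storage growth for one block size."""

    block_size: int
    seconds_per_element: float
    seconds_per_record: float
    db_growth_kb: float

    def __post_init__(self):
        if self.block_size <= 0:
            raise ValueError("block_size must be positive")
        for name in ("seconds_per_element", "seconds_per_record", "db_growth_kb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_seconds(self) -> float:
        return self.seconds_per_element * self.block_size


@dataclass(frozen=True)
class LinearityReport:
    """Fitted log-log scaling of total capture time vs block size."""

    slope: float
    intercept: float
    r_squared: float
    band: tuple[float, float]
    per_element_dispersion: float  # coefficient of variation of s/element

    @property
    def nearly_linear(self) -> bool:
        return self.band[0] <= self.slope <= self.band[1]


def run_runtime_experiment(
    store_factory: Callable[[int], ProvenanceStore],
    block_sizes: Sequence[int] = DEFAULT_BLOCKS,
    seed: int = 0,
) -> list[TimingRow]:
    """Populate a fresh store per block size and time the capture path.

    ``store_factory(block_size)`` must return a new, empty store (each
    block is isolated, mirroring per-machine isolation replayed
    sequentially).  Elements come from the built-in 7-type catalogue,
    spread round-robin across types.
    """
    if not block_sizes:
        raise ValueError("block_sizes must be non-empty")
    if any(b <= 0 for b in block_sizes):
        raise ValueError("block sizes must be positive")
    types = builtin_element_types()
    rows: list[TimingRow] = []
    for block in block_sizes:
        per_type = math.ceil(block / len(types))
        elements = list(islice(generate_elements(types, per_type, seed=seed), block))
        try:
            t_total0 = time.perf_counter()
            store = store_factory(block)
        except Exception as exc:
            raise RuntimeError(f"store_factory failed for block size {block}") from exc
        size_before = _db_size(store)
        session = store.open_session(
            pipeline_name=f"runtime_block_{block}",
            script=DEMO_SCRIPT, policy=DEMO_POLICY,
            steward=DEMO_STEWARD, owner=DEMO_OWNER,
        )
        t_loop0 = time.perf_counter()
        for el in elements:
            session.record(el)
        t_loop1 = time.perf_counter()
        session.close()
        store.close()
        t_total1 = time.perf_counter()
        size_after = _db_size(store)
        rows.append(TimingRow(
            block_size=block,
            seconds_per_element=(t_loop1 - t_loop0) / block,
            seconds_per_record=(t_total1 - t_total0) / block,
            db_growth_kb=max(0.0, (size_after - size_before) / 1024.0),
        ))
    return rows


def _db_size(store: ProvenanceStore) -> int:
    path = Path(store.location)
    if not path.exists():  # in-memory store
        return 0
    size = path.stat().st_size
    wal = path.with_name(path.name + "-wal")
    if wal.exists():
        size += wal.stat().st_size
    return size


def assess_linearity(
    rows: Sequence[TimingRow], band: tuple[float, float] = (0.8, 1.2)
) -> LinearityReport:
    """Fit log total time ~ slope * log block size; flag near-linearity.

    Requires >= 3 rows; a slope inside ``band`` (default 0.8–1.2) means
    capture time grows nearly linearly with input size.
    """
    if len(rows) < 3:
        raise ValueError("assess_linearity needs at least 3 timing rows")
    x = np.log([r.block_size for r in rows])
    y = np.log([max(r.total_seconds, 1e-12) for r in rows])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    per_el = np.array([r.seconds_per_element for r in rows])
    cv = float(per_el.std() / per_el.mean()) if per_el.mean() > 0 else 0.0
    return LinearityReport(slope=float(slope), intercept=float(intercept),
                           r_squared=r2, band=tuple(band), per_element_dispersion=cv)


def timing_table(rows: Sequence[TimingRow]) -> pd.DataFrame:
    """Timing rows as a DataFrame (one row per block size)."""
    return pd.DataFrame([{
        "block_size": r.block_size,
        "seconds_per_element": r.seconds_per_element,
        "seconds_per_record": r.seconds_per_record,
        "total_seconds": r.total_seconds,
        "db_growth_kb": r.db_growth_kb,
    } for r in rows])


def write_timing_csv(rows: Sequence[TimingRow], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    timing_table(rows).to_csv(path, index=False)
    return path


def plot_timing(rows: Sequence[TimingRow], path: str | Path) -> Path:
    """Log-log plot of total time and per-element time vs block size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = timing_table(rows)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.loglog(df.block_size, df.total_seconds, "o-", label="total capture time [s]")
    ax.loglog(df.block_size, df.seconds_per_element, "s--", label="time per element [s]")
    ax.set_xlabel("block size (elements)")
    ax.set_ylabel("seconds")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
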