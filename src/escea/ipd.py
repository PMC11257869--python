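"""Reconstruction of pseudo-individual patient data from digitized
Kaplan-Meier curves and numbers-at-risk tables.

Published survival curves carry more information than the summary statistics
usually quoted alongside them.  Given the digitized step coordinates of a KM
curve and the number-at-risk row printed beneath it, the interval-wise
inversion implemented here recovers a set of event and censoring times whose
product-limit estimate matches the published curve — "pseudo-IPD" suitable
for parametric model fitting.

Within each at-risk interval the algorithm alternates between (a) inverting
the product-limit ratios to get event counts at the digitized drop times,
given a provisional number of censorings interleaved uniformly over the
interval, and (b) updating the censoring count so that the implied number at
risk at the start of the next interval matches the published one.  Events
plus censorings in an interval always equal the published decrease in the
number at risk (conservation).  Censor times are placed deterministically
(uniform spacing), so reconstruction is reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
import numpy as np

__all__ = [
    "DigitizedKM",
    "PseudoIPD",
    "KMCurve",
    "reconstruct_ipd",
    "km_estimate",
    "read_digitized_km",
    "write_ipd_csv",
    "read_ipd_csv",
]


@dataclass(frozen=True)
class DigitizedKM:
    """Digitized KM coordinates plus the number-at-risk table.

    ``points`` are (time, survival) pairs starting at (0, 1.0) with strictly
    increasing times and non-increasing survival.  ``risk_table`` rows are
    (time, n_at_risk) with non-increasing counts.
    """

    arm_label: str
    endpoint: str
    points: tuple[tuple[float, float], ...]
    risk_table: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        if self.endpoint not in ("PFS", "OS"):
            raise ValueError("endpoint must be 'PFS' or 'OS'")
        pts = tuple((float(t), float(s)) for t, s in self.points)
        rt = tuple((float(t), int(n)) for t, n in self.risk_table)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "risk_table", rt)
        if len(pts) < 1 or pts[0] != (0.0, 1.0):
            raise ValueError("first digitized point must be (0, 1.0)")
        t = np.array([p[0] for p in pts])
        s = np.array([p[1] for p in pts])
        if np.any(np.diff(t) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("digitized survival must be non-increasing")
        if np.any(s <= 0) or np.any(s > 1):
            raise ValueError("survival values must lie in (0, 1]")
        if len(rt) < 2:
            raise ValueError("risk table needs at least 2 rows")
        rtimes = np.array([r[0] for r in rt])
        rn = np.array([r[1] for r in rt])
        if np.any(np.diff(rtimes) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(rn < 0):
            raise ValueError("n_at_risk must be non-negative")
        if np.any(np.diff(rn) > 0):
            raise ValueError("n_at_risk must be non-increasing")


@dataclass(frozen=True)
class PseudoIPD:
    """Right-censored records: ``times`` > 0 with ``events`` in {0, 1}."""

    times: np.ndarray
    events: np.ndarray
    arm_label: str = ""
    endpoint: str = "OS"
    time_unit: str = "months"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        if t.shape != e.shape:
            raise ValueError("times and events must have equal length")
        if t.size == 0:
            raise ValueError("pseudo-IPD must be non-empty")
        if np.any(t <= 0):
            raise ValueError("all times must be > 0")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("events must be 0 or 1")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


@dataclass(frozen=True)
class KMCurve:
    """A right-continuous product-limit step function."""

    times: np.ndarray  # event times where the curve drops, increasing
    survival: np.ndarray  # value on [times[i], times[i+1])

    def at(self, t):
        """Step-function evaluation; S(t) = 1 for t < first drop."""
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t_arr, side="right")
        vals = np.concatenate([[1.0], self.survival])[idx]
        return float(vals) if np.ndim(t) == 0 else vals


def km_estimate(ipd: PseudoIPD) -> KMCurve:
    """Product-limit estimate of the survival function.

    Backed by :class:`lifelines.KaplanMeierFitter`; returned as a compact
    step function evaluable at arbitrary times.
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    return KMCurve(times=times[keep], survival=surv[keep])


# ---------------------------------------------------------------------------
# reconstruction


def _interval_alloc(n_start, n_target, s_run, click_t, click_s, t0, t1, interval_idx):
    """Allocate events at digitized drop times and censorings in (t0, t1].

    Returns (event_times, event_counts, censor_times, s_run_after).
    Raises ValueError when no non-negative allocation is consistent with the
    published decrease in the number at risk.
    """
    total_leave = n_start - n_target
    if total_leave < 0:
        raise ValueError(
            f"risk table inconsistent in interval {interval_idx} "
            f"({t0}, {t1}]: n_at_risk increases from {n_start} to {n_target}"
        )

    def simulate(n_cens):
        if n_cens > 0:
            c_times = t0 + (np.arange(n_cens) + 0.5) / n_cens * (t1 - t0)
        else:
            c_times = np.empty(0)
        n = n_start
        s = s_run
        d_counts = []
        prev = t0
        ci = 0
        for tk, sk in zip(click_t, click_s):
            while ci < len(c_times) and c_times[ci] < tk:
                n -= 1
                ci += 1
            if n <= 0 or s <= 0:
                d = 0
            else:
                d = int(round(n * (1.0 - min(sk / s, 1.0))))
                d = min(max(d, 0), n)
                s = s * (1.0 - d / n)
                n -= d
            d_counts.append(d)
            prev = tk
        n -= len(c_times) - ci
        return np.array(d_counts, dtype=int), n, s

    # fixed-point iteration on the censoring count
    n_cens = 0
    d_counts, n_end, s_end = simulate(n_cens)
    for _ in range(60):
        n_cens_new = total_leave - int(d_counts.sum())
        n_cens_new = min(max(n_cens_new, 0), total_leave)
        if n_cens_new == n_cens:
            break
        n_cens = n_cens_new
        d_counts, n_end, s_end = simulate(n_cens)
    total_events = int(d_counts.sum())
    if total_events > total_leave:
        raise ValueError(
            f"risk table inconsistent in interval {interval_idx} ({t0}, {t1}]: "
            f"curve drops imply {total_events} events but the number at risk "
            f"only decreases by {total_leave}"
        )
    n_cens = total_leave - total_events
    if n_cens > 0:
        censor_times = t0 + (np.arange(n_cens) + 0.5) / n_cens * (t1 - t0)
    else:
        censor_times = np.empty(0)
    return np.asarray(click_t, dtype=float), d_counts, censor_times, s_end


def reconstruct_ipd(km: DigitizedKM) -> PseudoIPD:
    """Invert a digitized KM curve into event/censor times.

    One record is produced per patient initially at risk.  Drops of the
    digitized curve at time t are attributed to the at-risk interval
    (t_j, t_{j+1}] that contains t; patients remaining after the last
    digitized time are censored administratively at the end of follow-up.
    """
    pts_t = np.array([p[0] for p in km.points])
    pts_s = np.array([p[1] for p in km.points])
    risk_t = np.array([r[0] for r in km.risk_table])
    risk_n = np.array([r[1] for r in km.risk_table], dtype=int)

    event_times: list[float] = []
    censor_times: list[float] = []
    s_run = 1.0
    n_cur = int(risk_n[0])

    for j in range(len(risk_t) - 1):
        t0, t1 = risk_t[j], risk_t[j + 1]
        mask = (pts_t > t0) & (pts_t <= t1)
        ct, dc, cens, s_run = _interval_alloc(
            n_cur, int(risk_n[j + 1]), s_run, pts_t[mask], pts_s[mask], t0, t1, j
        )
        for tk, d in zip(ct, dc):
            event_times.extend([float(tk)] * int(d))
        censor_times.extend(float(c) for c in cens)
        n_cur = int(risk_n[j + 1])

    # digitized drops beyond the last risk-table time: no interleaved
    # censoring assumed (censoring only after the last event)
    tail_mask = pts_t > risk_t[-1]
    last_time = float(risk_t[-1])
    if np.any(tail_mask):
        for tk, sk in zip(pts_t[tail_mask], pts_s[tail_mask]):
            if n_cur <= 0 or s_run <= 0:
                break
            d = int(round(n_cur * (1.0 - min(sk / s_run, 1.0))))
            d = min(max(d, 0), n_cur)
            if d > 0:
                s_run *= 1.0 - d / n_cur
                event_times.extend([float(tk)] * d)
                n_cur -= d
            last_time = float(tk)
        last_time = float(pts_t[-1])
    # administrative censoring of everyone still at risk
    censor_times.extend([max(last_time, risk_t[-1])] * n_cur)

    times = np.array(event_times + censor_times)
    events = np.array([1] * len(event_times) + [0] * len(censor_times))
    order = np.argsort(times, kind="stable")
    return PseudoIPD(
        times=times[order],
        events=events[order],
        arm_label=km.arm_label,
        endpoint=km.endpoint,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_digitized_km(
    points_csv: str | Path,
    risk_csv: str | Path,
    arm_label: str = "",
    endpoint: str = "OS",
) -> DigitizedKM:
    """Read coordinates (columns time, survival) and a risk table
    (columns time, n_at_risk)."""
    import pandas as pd

    pts = pd.read_csv(points_csv)
    rt = pd.read_csv(risk_csv)
    return DigitizedKM(
        arm_label=arm_label,
        endpoint=endpoint,
        points=tuple(zip(pts["time"], pts["survival"])),
        risk_table=tuple(zip(rt["time"], rt["n_at_risk"])),
    )


def write_ipd_csv(ipd: PseudoIPD, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "event"])
        for t, e in zip(ipd.times, ipd.events):
            w.writerow([f"{t:.10g}", int(e)])


def read_ipd_csv(path: str | Path, **kwargs) -> PseudoIPD:
    import pandas as pd

    df = pd.read_csv(path)
    return PseudoIPD(times=df["time"].to_numpy(), events=df["event"].to_numpy(), **kwargs)
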