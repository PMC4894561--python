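"""Reconstruct pseudo individual-patient data from a digitized KM curve.

Implements the iterative inversion scheme of Guyot et al. (2012): within
each interval between consecutive numbers-at-risk reporting times,
censoring is assumed uniformly spread; the per-step death counts are
then solved so that (a) the product-limit estimate recomputed from the
reconstruction matches the digitized curve at every coordinate and (b)
the implied at-risk counts match the published risk table.

The stage is fully deterministic: given the same curve and risk table it
always returns the same patient records.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import KMCurve, PseudoIPD, RiskTable
from .synthetic import interval_counts_from_ipd

__all__ = ["reconstruct_ipd", "bin_monthly", "ReconstructionError"]

logger = logging.getLogger(__name__)

_MAX_ADJUST = 200  # cap on censoring-adjustment sweeps per interval


class ReconstructionError(ValueError):
    """Digitized curve and risk table cannot be reconciled."""


def _augment_curve(curve: KMCurve, risk_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Insert a (time, current survival) coordinate at each risk time.

    Redundant points do not change the step function but guarantee that
    every inter-risk-table interval opens with a digitized coordinate.
    """
    t = curve.times.copy()
    s = curve.survival.copy()
    for rt in risk_times:
        if rt > t[-1]:
            t = np.append(t, rt)
            s = np.append(s, s[-1])
        elif not np.any(np.isclose(t, rt, rtol=0, atol=1e-9)):
            pos = int(np.searchsorted(t, rt, side="right"))
            t = np.insert(t, pos, rt)
            s = np.insert(s, pos, s[pos - 1])
    return t, s


def reconstruct_ipd(
    curve: KMCurve,
    risk: RiskTable,
    total_events: int | None = None,
) -> PseudoIPD:
    """Invert a digitized KM curve plus risk table into patient records.

    Parameters
    ----------
    curve
        Digitized step-function coordinates, starting at ``(0, 1)``.
    risk
        Numbers at risk at scheduled times; must start at time 0.  Counts
        may follow either boundary convention (deaths falling exactly on
        a reporting time counted as at risk there, or already removed).
    total_events
        Reported total number of deaths, if available.  Censoring in the
        final reporting interval is re-balanced to match it.

    Returns
    -------
    PseudoIPD
        One record per patient implied by the initial at-risk count:
        deaths at their digitized step times, censorings spread uniformly
        within their reporting interval, survivors censored at the end of
        the curve.
    """
    if risk.times[0] != 0:
        raise ValueError("risk table must report the initial count at time 0")
    t_s, s = _augment_curve(curve, risk.times)
    K = t_s.size
    R = len(risk)
    n_risk = risk.n_at_risk.astype(int).copy()

    # index of the curve coordinate sitting exactly at each reporting time
    lower = np.array(
        [int(np.argmin(np.abs(t_s - rt))) for rt in risk.times], dtype=int
    )
    upper = np.append(lower[1:] - 1, K - 1)

    n_hat = np.zeros(K + 1, dtype=int)
    n_event = np.zeros(K, dtype=int)
    cens_times: list[np.ndarray] = [np.empty(0)] * R
    # at-risk count to open each interval with; adjusted when the table
    # reports counts net of deaths occurring exactly at the boundary
    risk_start = n_risk.astype(int).copy()
    km_last = 1.0  # product-limit value after the most recent event step

    def sweep(i: int, n_cen: int, km_in: float) -> tuple[int, float]:
        """Process interval i assuming ``n_cen`` censorings spread uniformly.

        Returns the implied at-risk count just before the next reporting
        time's coordinate, and the updated product-limit value.
        """
        lo, hi = lower[i], upper[i]
        t_end = t_s[lower[i + 1]] if i < R - 1 else t_s[-1]
        if n_cen > 0:
            ct = t_s[lo] + (np.arange(1, n_cen + 1) / (n_cen + 1)) * (t_end - t_s[lo])
        else:
            ct = np.empty(0)
        edges = np.append(t_s[lo : hi + 1], max(t_end, t_s[hi] + 1e-9))
        c = np.histogram(ct, bins=edges)[0] if n_cen > 0 else np.zeros(hi - lo + 1, int)
        cens_times[i] = ct
        n_hat[lo] = risk_start[i]
        km = km_in
        for k in range(lo, hi + 1):
            if k == 0 or n_hat[k] <= 0:
                n_event[k] = 0
            else:
                n_event[k] = int(np.rint(n_hat[k] * (1.0 - s[k] / km)))
                n_event[k] = min(max(n_event[k], 0), n_hat[k])
                if n_event[k] > 0:
                    km *= 1.0 - n_event[k] / n_hat[k]
            n_hat[k + 1] = max(n_hat[k] - n_event[k] - c[k - lo], 0)
        return int(n_hat[hi + 1]), km

    def boundary_deaths(implied: int, i_next: int, km: float) -> int:
        """Provisional death count at the coordinate opening interval i_next."""
        if implied <= 0 or km <= 0:
            return 0
        d = int(np.rint(implied * (1.0 - s[lower[i_next]] / km)))
        return min(max(d, 0), implied)

    for i in range(R - 1):
        lo, nxt = lower[i], lower[i + 1]
        if risk_start[i] <= 0:
            cens_times[i] = np.empty(0)
            n_hat[lo : nxt + 1] = 0
            n_event[lo:nxt] = 0
            continue
        if km_last <= 0:
            raise ReconstructionError(
                f"interval {i} ({risk.times[i]}-{risk.times[i + 1]} months): "
                f"survival already 0 but {risk_start[i]} patients reported at risk"
            )
        if s[lo] > 0:
            n_cen = int(np.rint(risk_start[i] * s[nxt] / s[lo])) - int(n_risk[i + 1])
        else:
            n_cen = 0
        if n_cen < 0:
            logger.warning(
                "interval %d (%g-%g months): implied censoring %d < 0; clamped to 0",
                i, risk.times[i], risk.times[i + 1], n_cen,
            )
            n_cen = 0
        matched = False
        for _ in range(_MAX_ADJUST):
            implied, km_out = sweep(i, n_cen, km_last)
            diff = implied - int(n_risk[i + 1])
            if diff == 0:
                matched = True
                break
            # the published count may be net of deaths at the boundary itself
            d_boundary = boundary_deaths(implied, i + 1, km_out)
            if d_boundary and implied - d_boundary == int(n_risk[i + 1]):
                risk_start[i + 1] = implied
                matched = True
                break
            if diff < 0 and n_cen <= 0:
                break
            n_cen = max(n_cen + diff, 0)
        else:
            raise ReconstructionError(
                f"interval {i} ({risk.times[i]}-{risk.times[i + 1]} months): "
                "could not reconcile the risk table with the survival drops"
            )
        if not matched and km_out <= 0 and n_risk[i + 1] > 0:
            raise ReconstructionError(
                f"interval {i} ({risk.times[i]}-{risk.times[i + 1]} months): curve "
                f"reaches survival 0 but the table reports {int(n_risk[i + 1])} at risk"
            )
        if not matched and implied < n_risk[i + 1]:
            # curve forces more departures than the published table admits
            logger.warning(
                "interval %d: implied at-risk %d below published %d; table relaxed",
                i, implied, int(n_risk[i + 1]),
            )
            risk_start[i + 1] = implied
        km_last = km_out

    # final interval: no closing risk-table constraint
    i = R - 1
    if risk_start[i] > 0:
        if km_last <= 0:
            raise ReconstructionError(
                f"final interval (from {risk.times[i]} months): survival already 0 "
                f"but {risk_start[i]} patients reported at risk"
            )
        if total_events is not None:
            events_before = int(n_event[: lower[i]].sum())
            target = total_events - events_before
            if target < 0:
                raise ReconstructionError(
                    f"total_events={total_events} below the {events_before} "
                    "events already implied before the final interval"
                )
            best_gap, best_cen = None, 0
            for n_cen in range(int(risk_start[i]) + 1):
                _, _ = sweep(i, n_cen, km_last)
                gap = abs(int(n_event[lower[i] :].sum()) - target)
                if best_gap is None or gap < best_gap:
                    best_gap, best_cen = gap, n_cen
                if gap == 0:
                    break
            _, km_last = sweep(i, best_cen, km_last)
        else:
            _, km_last = sweep(i, 0, km_last)

    # assemble patient records
    times: list[float] = []
    events: list[int] = []
    for k in range(K):
        if n_event[k]:
            times.extend([float(t_s[k])] * int(n_event[k]))
            events.extend([1] * int(n_event[k]))
    for ct in cens_times:
        times.extend(ct.tolist())
        events.extend([0] * ct.size)
    leftover = int(n_hat[-1])
    if leftover > 0:
        times.extend([float(t_s[-1])] * leftover)
        events.extend([0] * leftover)
    order = np.argsort(times, kind="stable")
    t_arr = np.maximum(np.asarray(times, dtype=float)[order], 1e-9)
    return PseudoIPD(t_arr, np.asarray(events, dtype=int)[order], arm_label=curve.arm_label)


def bin_monthly(
    ipd: PseudoIPD,
    study: str,
    treatment: str,
    horizon: float = 24.0,
    width: float = 1.0,
) -> pd.DataFrame:
    """Bin reconstructed records into labelled monthly interval counts.

    Bins are half-open ``[m, m+width)``; a death exactly on a boundary
    belongs to the later bin.  Patients still under observation at the
    horizon are censored in the final interval.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return interval_counts_from_ipd(
        ipd, study=study, treatment=treatment, width=width, horizon=horizon
    )
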