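"""Sleep-architecture metrics, NREM-cycle detection and stage/epoch masks.

All quantities follow the conventional polysomnography definitions: total
sleep time (TST) is the minutes spent in any of N1/N2/N3/REM between lights
off and lights on; sleep onset is the first non-wake epoch after lights off;
WASO counts wake between onset and the final awakening; sleep efficiency is
100·TST over the lights interval.  NREM/REM cycles are delimited by the
classical rule (a NREM period of at least 15 min followed by a REM period of
at least 5 min, the minimum being waived for the first REM period).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Hypnogram

SLEEP_STAGES = ("N1", "N2", "N3", "REM")
NREM_STAGES = ("N2", "N3")


@dataclass
class SleepArchitecture:
    tst_min: float
    waso_min: float
    sleep_efficiency: float
    sleep_latency_min: float
    rem_latency_min: float
    stage_pct: dict[str, float]
    first_cycle_min: float
    first_cycle_stage_pct: dict[str, float]

    def as_series(self) -> pd.Series:
        d = {
            "TST": self.tst_min,
            "WASO": self.waso_min,
            "SE": self.sleep_efficiency,
            "SL": self.sleep_latency_min,
            "REML": self.rem_latency_min,
            "N1": self.stage_pct["N1"],
            "N2": self.stage_pct["N2"],
            "N3": self.stage_pct["N3"],
            "REM": self.stage_pct["REM"],
            "Cyc1": self.first_cycle_min,
            "N1_cyc1": self.first_cycle_stage_pct["N1"],
            "N2_cyc1": self.first_cycle_stage_pct["N2"],
            "N3_cyc1": self.first_cycle_stage_pct["N3"],
        }
        return pd.Series(d)


@dataclass
class Cycle:
    index: int
    start_epoch: int
    end_epoch: int  # half-open
    nrem_epochs: int
    rem_epochs: int
    complete: bool = True

    @property
    def duration_min(self) -> float:
        return (self.end_epoch - self.start_epoch) * 0.5


def _epoch_min(hyp: Hypnogram) -> float:
    return hyp.epoch_s / 60.0


def sleep_onset_epoch(hyp: Hypnogram) -> int | None:
    """First non-W epoch at or after lights off, or None if never asleep."""
    first = int(np.ceil(hyp.lights_off / hyp.epoch_s))
    for i in range(first, len(hyp)):
        if hyp.stages[i] != "W":
            return i
    return None


def score_architecture(hyp: Hypnogram,
                       cyc1_denominator: str = "tst") -> SleepArchitecture:
    """Compute the standard whole-night sleep-architecture summary.

    Stage percentages are expressed as a share of TST; latencies are NaN when
    undefined (no sleep, or no REM).  First-cycle stage percentages use TST
    as denominator by default (``cyc1_denominator="cycle"`` divides by the
    cycle duration instead).
    """
    em = _epoch_min(hyp)
    stages = hyp.as_array()
    lights_min = (hyp.lights_on - hyp.lights_off) / 60.0

    onset = sleep_onset_epoch(hyp)
    sleep_mask = np.isin(stages, SLEEP_STAGES)
    tst = float(sleep_mask.sum()) * em

    if onset is None or tst == 0:
        nanpct = {s: float("nan") for s in SLEEP_STAGES}
        return SleepArchitecture(0.0, 0.0, 0.0, float("nan"), float("nan"),
                                 nanpct, float("nan"), dict(nanpct))

    sleep_latency = onset * em - hyp.lights_off / 60.0
    last_sleep = int(np.nonzero(sleep_mask)[0][-1])
    waso = float(np.sum(stages[onset:last_sleep + 1] == "W")) * em
    efficiency = 100.0 * tst / lights_min

    rem_idx = np.nonzero(stages == "REM")[0]
    rem_latency = (rem_idx[0] - onset) * em if len(rem_idx) else float("nan")

    stage_pct = {s: 100.0 * float(np.sum(stages == s)) * em / tst
                 for s in SLEEP_STAGES}

    cycles = detect_cycles(hyp)
    if cycles:
        c1 = cycles[0]
        cyc1_min = c1.duration_min if c1.complete else float("nan")
        sl = stages[c1.start_epoch:c1.end_epoch]
        denom = tst if cyc1_denominator == "tst" else c1.duration_min
        cyc1_pct = {s: 100.0 * float(np.sum(sl == s)) * em / denom
                    for s in SLEEP_STAGES}
    else:
        cyc1_min = float("nan")
        cyc1_pct = {s: float("nan") for s in SLEEP_STAGES}

    return SleepArchitecture(tst, waso, efficiency, sleep_latency, rem_latency,
                             stage_pct, cyc1_min, cyc1_pct)


def detect_cycles(hyp: Hypnogram, min_nrem_min: float = 15.0,
                  min_rem_min: float = 5.0) -> list[Cycle]:
    """Delimit NREM/REM cycles after sleep onset.

    A cycle ends at the end of a REM period that (a) follows at least
    ``min_nrem_min`` minutes of NREM since the cycle started and (b) lasts at
    least ``min_rem_min`` minutes — the latter waived for the first REM
    period.  If no qualifying REM period follows the last cycle start, a
    single trailing cycle is returned flagged incomplete.
    """
    onset = sleep_onset_epoch(hyp)
    if onset is None:
        return []
    em = _epoch_min(hyp)
    stages = hyp.as_array()
    last_sleep = int(np.nonzero(np.isin(stages, SLEEP_STAGES))[0][-1])

    cycles: list[Cycle] = []
    start = onset
    i = onset
    n = last_sleep + 1
    while i < n:
        if stages[i] == "REM":
            j = i
            while j < n and stages[j] == "REM":
                j += 1
            rem_len = (j - i) * em
            nrem_len = float(np.sum(np.isin(stages[start:i], NREM_STAGES))) * em
            first = not cycles
            if nrem_len >= min_nrem_min and (first or rem_len >= min_rem_min):
                seg = stages[start:j]
                cycles.append(Cycle(
                    index=len(cycles) + 1, start_epoch=start, end_epoch=j,
                    nrem_epochs=int(np.sum(np.isin(seg, NREM_STAGES))),
                    rem_epochs=j - i))
                start = j
            i = j
        else:
            i += 1
    if start < n:
        seg = stages[start:n]
        cycles.append(Cycle(
            index=len(cycles) + 1, start_epoch=start, end_epoch=n,
            nrem_epochs=int(np.sum(np.isin(seg, NREM_STAGES))),
            rem_epochs=int(np.sum(seg == "REM")), complete=False))
    return cycles


@dataclass
class EpochSelection:
    """Per-channel x per-epoch boolean selection (True = analysed).

    The product of stage membership, an optional cycle restriction, and an
    optional per-channel artifact-retention mask.
    """

    mask: np.ndarray  # (n_channels, n_epochs) bool
    epoch_s: float = 30.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("selection mask must be 2-D")

    @property
    def n_channels(self) -> int:
        return self.mask.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.mask.shape[1]

    def minutes(self) -> np.ndarray:
        """Retained minutes per channel."""
        return self.mask.sum(axis=1) * self.epoch_s / 60.0

    def sample_mask(self, fs: float, n_samples: int | None = None) -> np.ndarray:
        spe = int(round(self.epoch_s * fs))
        full = np.repeat(self.mask, spe, axis=1)
        if n_samples is not None:
            if n_samples < full.shape[1]:
                full = full[:, :n_samples]
            elif n_samples > full.shape[1]:
                pad = np.zeros((self.n_channels, n_samples - full.shape[1]), bool)
                full = np.concatenate([full, pad], axis=1)
        return full


def stage_mask(hyp: Hypnogram, stages, n_channels: int,
               cycle: Cycle | None = None,
               epoch_mask: np.ndarray | None = None) -> EpochSelection:
    """Build the epoch selection for the requested stages/cycle/artifact mask.

    Raises if the intersection is empty on every channel, naming the first
    constraint that emptied it.
    """
    stages = tuple(stages)
    st = np.isin(hyp.as_array(), stages)
    if not st.any():
        raise ValueError(f"no epochs in stages {stages}")
    sel = np.tile(st, (n_channels, 1))
    if cycle is not None:
        cyc = np.zeros(len(hyp), dtype=bool)
        cyc[cycle.start_epoch:cycle.end_epoch] = True
        sel &= cyc
        if not sel.any():
            raise ValueError(f"stages {stages} do not intersect cycle {cycle.index}")
    if epoch_mask is not None:
        epoch_mask = np.asarray(epoch_mask, dtype=bool)
        if epoch_mask.shape != sel.shape:
            raise ValueError("artifact mask shape does not match selection")
        sel &= epoch_mask
        if not sel.any():
            raise ValueError("artifact rejection removed every selected epoch")
    return EpochSelection(mask=sel, epoch_s=hyp.epoch_s)


def compare_architecture(group_a: list[SleepArchitecture],
                         group_b: list[SleepArchitecture]) -> pd.DataFrame:
    """Two-group comparison of architecture parameters.

    Returns per parameter the group means and standard errors, the absolute
    difference (A − B), the relative difference as a percentage of the
    group-B mean, and the unpaired two-sample t statistic with its p-value.
    """
    from .stats_topo import unpaired_t

    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    ta = pd.DataFrame([a.as_series() for a in group_a])
    tb = pd.DataFrame([b.as_series() for b in group_b])
    rows = []
    for col in ta.columns:
        a, b = ta[col].to_numpy(float), tb[col].to_numpy(float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            rows.append((col, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                         np.nan, np.nan))
            continue
        ma, mb = a.mean(), b.mean()
        sea = a.std(ddof=1) / np.sqrt(len(a))
        seb = b.std(ddof=1) / np.sqrt(len(b))
        t, _, p = unpaired_t(a, b)
        rel = 100.0 * (ma - mb) / mb if mb != 0 else np.nan
        rows.append((col, ma, sea, mb, seb, ma - mb, rel, t, p))
    return pd.DataFrame(rows, columns=[
        "parameter", "mean_a", "se_a", "mean_b", "se_b",
        "diff", "rel_diff_pct", "t", "p"]).set_index("parameter")
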