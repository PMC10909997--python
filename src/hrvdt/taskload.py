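"""Subjective workload (weighted NASA-TLX) and n-back performance scoring."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .synth import TLX_DIMENSIONS, ResponseLog

#: number of unordered dimension pairs in the weighting procedure
N_PAIRS = 15


@dataclass(frozen=True)
class TLXResponse:
    """Six ratings on the 21-point scale (stored 0-20) plus 15 pairwise choices.

    ``pair_choices`` holds one entry per unordered dimension pair: the pair
    and the dimension the respondent judged the more important contributor.
    """

    ratings: dict[str, int]
    pair_choices: tuple[tuple[tuple[str, str], str], ...]
    scale_offset: int = 0      # set to 1 for 1-21 storage

    def __post_init__(self):
        if set(self.ratings) != set(TLX_DIMENSIONS):
            raise ValueError("ratings must cover exactly the six TLX dimensions")
        lo, hi = self.scale_offset, self.scale_offset + 20
        for d, r in self.ratings.items():
            if not lo <= r <= hi:
                raise ValueError(f"rating for {d} outside the 21-point scale")
        expected = {frozenset(p) for p in itertools.combinations(TLX_DIMENSIONS, 2)}
        got = [frozenset(pair) for pair, _ in self.pair_choices]
        if len(got) != N_PAIRS or set(got) != expected:
            raise ValueError("pair_choices must list each unordered dimension pair once")
        for pair, chosen in self.pair_choices:
            if chosen not in pair:
                raise ValueError(f"chosen dimension {chosen!r} not in its pair {pair}")

    def selection_counts(self) -> dict[str, int]:
        counts = {d: 0 for d in TLX_DIMENSIONS}
        for _, chosen in self.pair_choices:
            counts[chosen] += 1
        return counts


def tlx_weights(response: TLXResponse) -> dict[str, float]:
    """Selection-frequency weights 1/21 ... 6/21 assigned by ascending rank.

    Dimensions tied on selection count share the mean of the weights their
    rank positions span (the average-rank convention), so the six weights
    always sum to exactly 1 (ranks sum to 21).
    """
    counts = response.selection_counts()
    ranks = rankdata([counts[d] for d in TLX_DIMENSIONS], method="average")
    return {d: r / 21.0 for d, r in zip(TLX_DIMENSIONS, ranks)}


def score_tlx(response: TLXResponse) -> float:
    """Weighted total workload: sum of weight x rating over the six dimensions."""
    w = tlx_weights(response)
    return float(sum(w[d] * response.ratings[d] for d in TLX_DIMENSIONS))


@dataclass(frozen=True)
class PerformanceSummary:
    """RT statistics over hits plus reaction-ratio indicators for one run.

    RT fields are ``None`` when there were no hits.  CNR + MNR = 1 over the
    targets; WNR is the false-alarm rate over non-target stimuli.
    """

    MRT: float | None
    SDRT: float | None
    maxRT: float | None
    minRT: float | None
    CNR: float
    MNR: float
    WNR: float
    n_targets: int
    n_hits: int

    def __post_init__(self):
        if abs(self.CNR + self.MNR - 1.0) > 1e-12:
            raise ValueError("CNR + MNR must equal 1")
        if self.MRT is not None and not self.minRT <= self.MRT <= self.maxRT:
            raise ValueError("need minRT <= MRT <= maxRT")


def score_performance(logs: ResponseLog | list[ResponseLog] | tuple[ResponseLog, ...]
                      ) -> PerformanceSummary:
    """Aggregate one or more trial logs into the seven performance indices.

    A hit is a target with a response inside the response window; RT
    statistics are computed over hit RTs only (SDRT with the sample n-1
    denominator, undefined-marked with a single hit).
    """
    log_list = [logs] if isinstance(logs, ResponseLog) else list(logs)
    events = [e for lg in log_list for e in lg.events]
    targets = [e for e in events if e.is_target]
    non_targets = [e for e in events if not e.is_target]
    if not targets:
        raise ValueError("log contains no targets")
    hit_rts = np.array([e.rt_ms for e in targets if e.responded and e.rt_ms is not None])
    n_hits = len(hit_rts)
    cnr = n_hits / len(targets)
    wnr = (sum(e.responded for e in non_targets) / len(non_targets)
           if non_targets else 0.0)
    if n_hits:
        mrt = float(np.mean(hit_rts))
        sdrt = float(np.std(hit_rts, ddof=1)) if n_hits > 1 else None
        max_rt, min_rt = float(np.max(hit_rts)), float(np.min(hit_rts))
    else:
        mrt = sdrt = max_rt = min_rt = None
    return PerformanceSummary(MRT=mrt, SDRT=sdrt, maxRT=max_rt, minRT=min_rt,
                              CNR=cnr, MNR=1.0 - cnr, WNR=wnr,
                              n_targets=len(targets), n_hits=n_hits)


def performance_as_dict(summary: PerformanceSummary) -> dict[str, float]:
    nan = float("nan")
    return {"MRT": summary.MRT if summary.MRT is not None else nan,
            "SDRT": summary.SDRT if summary.SDRT is not None else nan,
            "maxRT": summary.maxRT if summary.maxRT is not None else nan,
            "minRT": summary.minRT if summary.minRT is not None else nan,
            "CNR": summary.CNR, "MNR": summary.MNR, "WNR": summary.WNR}
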