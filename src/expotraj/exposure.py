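"""Annual exposure-intensity series and lifetime summary metrics.

Builds per-subject annual intensity series from raw exposure histories —
either directly reported episodes (e.g. smoking, in cigarettes/day) or
job-coded episodes valued through a job-exposure matrix (JEM) — on a
backward time axis (years before the index date, 0 = index year).  Provides
the lifetime summary metrics used downstream: the cumulative index of
exposure (CIE, f/mL-years, or cigarette-years for smoking), the
comprehensive smoking index (CSI), and the a-priori partition of
low-cumulative-exposure subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExposureEpisode",
    "JEMEntry",
    "AnnualSeries",
    "SubjectRecord",
    "CSIParams",
    "annual_level_from_jobs",
    "build_series",
    "cumulative_index",
    "csi",
    "low_exposure_partition",
]


@dataclass(frozen=True)
class ExposureEpisode:
    """One exposure episode: a calendar interval with an intensity or a job code.

    For directly reported exposures (smoking) ``intensity`` is the average
    daily amount over the episode; for occupational exposures ``job_code``
    identifies the occupation x activity combination to be valued through a
    JEM, and ``intensity`` is ignored.
    """

    start_year: int
    end_year: int
    intensity: float = 0.0
    job_code: str | None = None

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError(
                f"episode ends ({self.end_year}) before it starts ({self.start_year})"
            )
        if self.intensity < 0:
            raise ValueError("episode intensity must be non-negative")


@dataclass(frozen=True)
class JEMEntry:
    """One JEM cell: job code x calendar period -> (probability, frequency, intensity).

    Probability is the proportion of exposed workers in the job, frequency
    the proportion of exposed working time on a typical 8-h day, intensity
    the equivalent average concentration (f/mL) at the workplace.
    """

    job_code: str
    period_start: int
    period_end: int
    probability: float
    frequency: float
    intensity: float

    def __post_init__(self) -> None:
        if self.period_end < self.period_start:
            raise ValueError("JEM period ends before it starts")
        if not 0.0 <= self.probability <= 0.85:
            raise ValueError(f"JEM probability {self.probability} outside [0, 0.85]")
        if not 0.025 <= self.frequency <= 0.85:
            raise ValueError(f"JEM frequency {self.frequency} outside [0.025, 0.85]")
        if not 0.0005 <= self.intensity <= 20.0:
            raise ValueError(f"JEM intensity {self.intensity} outside [0.0005, 20]")

    @property
    def level(self) -> float:
        """Annual exposure level for this job: intensity x probability x frequency."""
        return self.intensity * self.probability * self.frequency

    def contains(self, year: int) -> bool:
        return self.period_start <= year <= self.period_end


@dataclass
class AnnualSeries:
    """One subject's annual exposure intensities on the years-before-index axis.

    ``times`` are integer years before the index date (0 = index year),
    strictly monotone with no duplicates; the series spans the window from
    first exposure to the index date, with interruption years carrying 0.
    """

    subject_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if self.times.size:
            d = np.diff(self.times)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("times must be strictly monotone with no duplicates")
            if np.any(self.times < 0):
                raise ValueError("times before the index date must be >= 0")
        if np.any(self.values < 0):
            raise ValueError("annual intensities must be non-negative")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    outcome: int
    age_at_index: float
    stratum: str
    never_exposed: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be 0 (control) or 1 (case)")


@dataclass(frozen=True)
class CSIParams:
    """Half-life (tau, years) and lag (delta, years) of the comprehensive smoking index."""

    half_life: float
    lag: float = 0.0

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("CSI half-life must be > 0")
        if self.lag < 0:
            raise ValueError("CSI lag must be >= 0")


def annual_level_from_jobs(jobs_in_year: list[JEMEntry], year: int) -> float:
    """Mean annual exposure level over all jobs held in ``year``.

    Each job contributes intensity x probability x frequency; concurrent jobs
    in one calendar year are averaged.
    """
    if not jobs_in_year:
        raise ValueError(f"no job held in year {year}")
    for e in jobs_in_year:
        if not e.contains(year):
            raise ValueError(
                f"year {year} outside JEM period [{e.period_start}, {e.period_end}] "
                f"for job {e.job_code!r}"
            )
    return float(np.mean([e.level for e in jobs_in_year]))


def _jem_lookup(jem: list[JEMEntry], job_code: str, year: int) -> JEMEntry:
    hits = [e for e in jem if e.job_code == job_code and e.contains(year)]
    if not hits:
        raise ValueError(f"no JEM entry for job {job_code!r} in year {year}")
    if len(hits) > 1:
        raise ValueError(f"overlapping JEM periods for job {job_code!r} in year {year}")
    return hits[0]


def build_series(
    episodes: list[ExposureEpisode],
    jem: list[JEMEntry] | None,
    index_year: int,
    subject_id: str = "",
) -> AnnualSeries:
    """Annual intensity series from first exposure year to the index date.

    A calendar year inside an episode carries the episode intensity (any
    part-year at full intensity, since the time unit is the year); years in
    no episode carry 0.  Concurrent directly-reported episodes are summed
    (an average daily total); concurrent job-coded episodes are averaged
    over jobs after valuing each through the JEM.  Times are returned as
    years before the index date, increasing into the past.
    """
    if not episodes:
        raise ValueError("no exposure episodes: subject is never exposed")
    if any(e.end_year > index_year for e in episodes):
        raise ValueError("exposure episode extends past the index date")
    job_mode = any(e.job_code is not None for e in episodes)
    if job_mode and any(e.job_code is None for e in episodes):
        raise ValueError("cannot mix job-coded and directly-reported episodes")
    if job_mode and jem is None:
        raise ValueError("job-coded episodes require a JEM")

    first = min(e.start_year for e in episodes)
    years = np.arange(first, index_year + 1)
    values = np.zeros(years.size)
    for i, yr in enumerate(years):
        active = [e for e in episodes if e.start_year <= yr <= e.end_year]
        if not active:
            continue
        if job_mode:
            entries = [_jem_lookup(jem, e.job_code, int(yr)) for e in active]
            values[i] = annual_level_from_jobs(entries, int(yr))
        else:
            values[i] = sum(e.intensity for e in active)
    t_before = index_year - years  # increasing into the past after reversal
    return AnnualSeries(subject_id, t_before[::-1].copy(), values[::-1].copy())


def cumulative_index(series: AnnualSeries) -> float:
    """Cumulative index of exposure: sum of annual intensities (f/mL-years
    for asbestos, cigarette-years for smoking)."""
    return float(np.sum(series.values))


def csi(
    duration: float,
    time_since_cessation: float,
    avg_intensity: float,
    params: CSIParams,
) -> float:
    """Comprehensive smoking index.

    CSI = (1 - 0.5^(d*/tau)) * 0.5^(t*/tau) * ln(intensity + 1), where the
    lag-adjusted duration d* = max(0, duration - max(0, delta - tsc)) and
    lag-adjusted time since cessation t* = max(0, tsc - delta).  Zero for
    never smokers, increasing in duration and intensity, decaying with the
    half-life tau as time since cessation grows.
    """
    if duration < 0 or time_since_cessation < 0 or avg_intensity < 0:
        raise ValueError("CSI arguments must be non-negative")
    tau, delta = params.half_life, params.lag
    d_star = max(0.0, duration - max(0.0, delta - time_since_cessation))
    t_star = max(0.0, time_since_cessation - delta)
    return (1.0 - 0.5 ** (d_star / tau)) * 0.5 ** (t_star / tau) * math.log(
        avg_intensity + 1.0
    )


def low_exposure_partition(
    subject_ids: list[str],
    series_by_id: dict[str, AnnualSeries],
    cutoff: float,
) -> tuple[list[str], list[str]]:
    """Split ever-exposed subjects at the a-priori cumulative-exposure cutoff.

    Subjects with CIE strictly below ``cutoff`` form the a-priori
    low-exposure class; the rest (CIE >= cutoff, including exactly at the
    cutoff) are modelled with the latent class mixed model.  Subjects with
    no series (never exposed) belong to neither group.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    low, remaining = [], []
    for sid in subject_ids:
        s = series_by_id.get(sid)
        if s is None or len(s) == 0:
            continue
        (low if cumulative_index(s) < cutoff else remaining).append(sid)
    return low, remaining
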