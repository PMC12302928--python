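"""Peak QC, internal-standard semi-quantification and retention indices.

The preprocessing chain runs in a fixed order: peak-level QC filters,
internal-standard normalization (yielding *relative content*), the
missingness filter, then half-minimum imputation. Boundary semantics are
deliberate and asymmetric: QC thresholds are inclusive (S/N >= 50,
similarity >= 700), the missingness filter is strict (*more than* half
missing is removed, exactly half is kept), and retention-index confirmation
is strict (|delta RI| must be *less than* the tolerance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables_io import AlkaneLadder, FeatureTable, PeakRecord


@dataclass(frozen=True)
class QcThresholds:
    """Quality-control thresholds for peak retention and identity confirmation.

    ``min_sn``
        minimum signal-to-noise ratio (inclusive).
    ``min_similarity``
        minimum spectral library-match score, 0-999 scale (inclusive).
    ``max_missing_frac``
        features missing in strictly more than this fraction of samples are
        removed.
    ``ri_tolerance``
        |calculated RI - theoretical RI| must be strictly below this for a
        confirmed identity.
    """

    min_sn: float = 50.0
    min_similarity: float = 700.0
    max_missing_frac: float = 0.5
    ri_tolerance: float = 20.0

    def __post_init__(self) -> None:
        for name in ("min_sn", "min_similarity", "max_missing_frac", "ri_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"QcThresholds.{name} must be positive")


def filter_peaks(
    records: Sequence[PeakRecord], thresholds: QcThresholds = QcThresholds()
) -> tuple[list[str], pd.DataFrame]:
    """Retain peaks meeting both QC thresholds; report each rejection.

    Returns the retained feature ids (input order) and a rejection report
    with one row per rejected feature naming every failing criterion.
    """
    if not records:
        raise ValueError("no peak records to filter")
    retained: list[str] = []
    rejected: list[dict] = []
    for rec in records:
        reasons = []
        if rec.signal_to_noise < thresholds.min_sn:
            reasons.append("S/N")
        if rec.similarity < thresholds.min_similarity:
            reasons.append("similarity")
        if reasons:
            rejected.append(
                {
                    "feature_id": rec.feature_id,
                    "signal_to_noise": rec.signal_to_noise,
                    "similarity": rec.similarity,
                    "reason": "+".join(reasons),
                }
            )
        else:
            retained.append(rec.feature_id)
    report = pd.DataFrame(
        rejected, columns=["feature_id", "signal_to_noise", "similarity", "reason"]
    )
    return retained, report


def normalize_internal_standard(table: FeatureTable) -> FeatureTable:
    """Divide each sample's intensities by its internal-standard intensity.

    The result is the *relative content* used everywhere downstream
    (including odor-activity scoring). The internal-standard column, which
    would be identically 1, is dropped. Missing or zero internal-standard
    intensity in any sample is a hard error naming the sample.
    """
    is_id = table.internal_standard_id
    if is_id is None:
        raise ValueError("table has no internal_standard_id set")
    is_col = table.values[is_id]
    bad = [s for s, v in is_col.items() if pd.isna(v) or v <= 0]
    if bad:
        raise ValueError(
            f"internal standard {is_id!r} missing or non-positive in samples {bad}"
        )
    values = table.values.div(is_col, axis=0).drop(columns=[is_id])
    return replace(table, values=values, internal_standard_id=None)


def filter_missingness(
    table: FeatureTable, max_missing_frac: float = 0.5
) -> tuple[FeatureTable, list[str]]:
    """Remove features missing in strictly more than ``max_missing_frac``.

    A feature missing in exactly half of the samples is kept.
    """
    if not 0 <= max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in [0, 1)")
    frac = table.missing_fraction()
    removed = [f for f in table.feature_ids if frac[f] > max_missing_frac]
    return table.drop_features(removed), removed


def impute_half_min(table: FeatureTable) -> FeatureTable:
    """Replace each missing cell by half the feature's minimum observed value.

    Half-minimum is the conventional stand-in for values censored at the
    detection limit. Features with no observation at all should have been
    removed by the missingness filter and are an error here.
    """
    values = table.values.copy()
    empty = values.columns[values.notna().sum(axis=0) == 0].tolist()
    if empty:
        raise ValueError(f"features with zero observations cannot be imputed: {empty}")
    fill = values.min(axis=0, skipna=True) / 2.0
    return replace(table, values=values.fillna(fill))


def compute_ri(retention_time: float, ladder: AlkaneLadder) -> float:
    """Kovats-type retention index for temperature-programmed GC.

    Linear (van den Dool-Kratz) interpolation between the bracketing ladder
    alkanes: ``RI = 100*c_n + 100*(c_{n+1}-c_n)*(t-t_n)/(t_{n+1}-t_n)``.
    An alkane's own retention time maps exactly to 100x its carbon number.
    No extrapolation: times outside the ladder span are an error.
    """
    t = float(retention_time)
    if not math.isfinite(t):
        raise ValueError("retention_time must be finite")
    times = np.asarray(ladder.retention_times)
    carbons = np.asarray(ladder.carbon_numbers)
    lo, hi = ladder.span
    if t < lo or t > hi:
        raise ValueError(
            f"retention time {t} min outside ladder span [{lo}, {hi}] min"
        )
    # right-most bracket whose left anchor is <= t
    i = int(np.searchsorted(times, t, side="right")) - 1
    i = min(i, len(times) - 2)
    t0, t1 = times[i], times[i + 1]
    c0, c1 = carbons[i], carbons[i + 1]
    return 100.0 * c0 + 100.0 * (c1 - c0) * (t - t0) / (t1 - t0)


def compute_ri_many(
    retention_times: Iterable[float], ladder: AlkaneLadder
) -> np.ndarray:
    return np.array([compute_ri(t, ladder) for t in retention_times])


def confirm_identity(
    calculated_ri: float, theoretical_ri: float, ri_tolerance: float = 20.0
) -> bool:
    """Confirm an identification iff |calculated - theoretical| < tolerance."""
    if not (math.isfinite(calculated_ri) and math.isfinite(theoretical_ri)):
        raise ValueError("retention indices must be finite")
    return abs(calculated_ri - theoretical_ri) < ri_tolerance


def preprocess_table(
    table: FeatureTable,
    *,
    thresholds: QcThresholds = QcThresholds(),
    peaks: Sequence[PeakRecord] | None = None,
    annotations: pd.DataFrame | None = None,
    apply_missing_filter: bool = True,
) -> tuple[FeatureTable, dict]:
    """Run the full chain: QC -> IS normalization -> missingness -> imputation.

    ``peaks`` enables the peak-level S/N-similarity filter and, when
    ``annotations`` supply theoretical retention indices, the identity
    confirmation step. Returns the processed table and a log dict with the
    per-stage removals; applying the chain to its own output is a no-op.
    """
    log: dict = {"n_features_in": table.n_features}
    if peaks is not None:
        retained, report = filter_peaks(peaks, thresholds)
        known = set(retained)
        qc_removed = [
            f
            for f in table.feature_ids
            if f not in known and f != table.internal_standard_id
        ]
        if annotations is not None and "theoretical_ri" in annotations:
            by_id = {p.feature_id: p for p in peaks}
            for f in list(known):
                p = by_id.get(f)
                theo = (
                    annotations["theoretical_ri"].get(f)
                    if f in annotations.index
                    else None
                )
                if (
                    p is not None
                    and p.calculated_ri is not None
                    and theo is not None
                    and pd.notna(theo)
                    and not confirm_identity(
                        p.calculated_ri, float(theo), thresholds.ri_tolerance
                    )
                ):
                    known.discard(f)
                    qc_removed.append(f)
        table = table.drop_features(qc_removed)
        log["qc_removed"] = sorted(qc_removed)
        log["qc_report"] = report
    if table.internal_standard_id is not None:
        table = normalize_internal_standard(table)
        log["normalized"] = True
    if apply_missing_filter:
        table, removed = filter_missingness(table, thresholds.max_missing_frac)
        log["missingness_removed"] = removed
    table = impute_half_min(table)
    log["n_features_out"] = table.n_features
    return table, log
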