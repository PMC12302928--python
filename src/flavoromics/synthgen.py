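"""Synthetic three-breed study generator.

Emulates the statistical structure of a two-platform beef flavoromics
study — three breed groups (GL, SN, XZ) with a few biological replicates
each, a non-volatile metabolite table and a volatile-compound (VOC) table —
so every downstream stage is testable without any external download.

The generative model is deliberately simple and exactly controllable:

* log-intensity = sample effect + latent group mean + N(0, sigma), i.e.
  intensities are log-normal with multiplicative noise of coefficient of
  variation ``cv_noise`` (sigma^2 = ln(1 + cv^2));
* a planted subset of features receives a multiplicative fold change
  (``effect_size``, random direction) in exactly one affected group, so the
  latent log-mean difference is exactly ``+/- ln(effect_size)``;
* one internal-standard channel per table shares the per-sample effect and
  is never planted and never censored, so internal-standard normalization
  removes the sample effect by construction;
* below-detection censoring (values under a pooled intensity quantile) is
  applied before missing-at-random masking, mimicking detection-limit
  structure;
* the alkane ladder is affine in carbon number with jitter bounded by 1% of
  the per-carbon spacing, so the retention-index closed form is exact at
  zero jitter and near-exact otherwise.

Everything derives from one ``numpy`` generator seeded from ``SynthConfig.seed``:
identical configs give byte-identical studies.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path


import numpy as np
import pandas as pd

from . import preprocess
from .tables_io import (
    CHEMICAL_CLASSES,
    AlkaneLadder,
    FeatureTable,
    PeakRecord,
    validate_annotations,
    write_annotations,
    write_feature_table,
    write_ladder,
    write_pathways,
    write_peak_records,
)

GROUP_NAMES = ("GL", "SN", "XZ")

#: Sensory-descriptor vocabulary (includes the canonical network attributes).
SENSORY_VOCABULARY = (
    "sweet",
    "fruity",
    "green",
    "waxy",
    "ethereal",
    "floral",
    "fatty",
    "buttery",
    "almond",
    "cucumber",
    "rose",
    "nutty",
    "cocoa",
    "roasted",
    "sulfurous",
)

# Real VOC names (commas, parentheses, Greek letters) to exercise CSV quoting.
_NAME_POOL = (
    "2,3-Butanedione",
    "(E)-2-nonenal",
    "(E)-2-octenal",
    "2-ethyl-1-hexanol",
    "2-methyl-butanal",
    "acetophenone",
    "dimethyl sulfide",
    "hexanal",
    "1-octen-3-ol",
    "γ-nonalactone",
    "benzaldehyde",
    "2-pentylfuran",
    "nonanal",
    "ethyl hexanoate",
    "δ-decalactone",
)


@dataclass(frozen=True)
class SynthConfig:
    """Study-design knobs for :func:`generate_study`.

    Defaults mirror the emulated design: 3 breed groups x 3 replicates,
    ~10% of features carrying a 4-fold group effect under 20% multiplicative
    noise, with mild missing-at-random plus detection-limit censoring.
    Use ``n_per_group >= 20`` for power/recovery experiments.
    """

    n_groups: int = 3
    n_per_group: int = 3
    n_metabolites: int = 200
    n_vocs: int = 150
    frac_differential: float = 0.1
    effect_size: float = 4.0
    cv_noise: float = 0.2
    missing_rate: float = 0.10
    lod_quantile: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("SynthConfig.n_groups must be >= 2")
        if self.n_per_group < 2:
            raise ValueError("SynthConfig.n_per_group must be >= 2")
        if self.n_metabolites < 2 or self.n_vocs < 2:
            raise ValueError(
                "SynthConfig.n_metabolites and SynthConfig.n_vocs must be >= 2"
            )
        if not 0 <= self.frac_differential <= 1:
            raise ValueError("SynthConfig.frac_differential must be in [0, 1]")
        if self.effect_size <= 0:
            raise ValueError("SynthConfig.effect_size must be > 0")
        if self.cv_noise <= 0:
            raise ValueError("SynthConfig.cv_noise must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("SynthConfig.missing_rate must be in [0, 1)")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("SynthConfig.lod_quantile must be in [0, 1)")

    @property
    def group_names(self) -> tuple[str, ...]:
        extra = tuple(f"B{i}" for i in range(4, self.n_groups + 1))
        return (GROUP_NAMES + extra)[: self.n_groups]


@dataclass
class TruthRecord:
    """Ground truth of a synthetic study — the acceptance surface.

    ``planted`` maps table name ("metabolite" / "voc") to
    ``{feature_id: (affected_group, direction, fold)}`` with direction in
    {+1, -1} and fold equal to the configured effect size.
    ``latent_means`` holds the groups x features log-scale mean matrices.
    ``pathway_assignments`` maps metabolite feature id -> set of pathway ids;
    ``enriched_pathways`` names the pathways deliberately loaded with
    planted metabolites.
    """

    planted: dict[str, dict[str, tuple[str, int, float]]]
    latent_means: dict[str, pd.DataFrame]
    pathway_assignments: dict[str, set[str]]
    enriched_pathways: set[str]

    def differential_features(self, table: str | None = None) -> set[str]:
        if table is not None:
            return set(self.planted[table])
        return {f for d in self.planted.values() for f in d}


@dataclass
class SynthStudy:
    """Everything :func:`generate_study` produces, ready for the pipeline."""

    metabolites: FeatureTable
    vocs: FeatureTable
    annotations: pd.DataFrame
    ladder: AlkaneLadder
    pathways: dict[str, set[str]]
    voc_peaks: list[PeakRecord]
    truth: TruthRecord
    config: SynthConfig


def make_ladder(
    c_min: int = 7,
    c_max: int = 30,
    t0: float = 5.0,
    minutes_per_carbon: float = 1.8,
    jitter_frac: float = 0.01,
    rng: np.random.Generator | None = None,
) -> AlkaneLadder:
    """Affine temperature-program alkane ladder with bounded jitter.

    ``retention_time = t0 + minutes_per_carbon * (c - c_min) + jitter`` with
    |jitter| <= ``jitter_frac`` x spacing, so monotonicity is guaranteed for
    ``jitter_frac < 0.5`` and the interpolation is exactly linear at 0.
    """
    carbons = np.arange(c_min, c_max + 1)
    times = t0 + minutes_per_carbon * (carbons - c_min)
    if jitter_frac > 0:
        rng = rng or np.random.default_rng(0)
        times = times + rng.uniform(
            -jitter_frac * minutes_per_carbon,
            jitter_frac * minutes_per_carbon,
            size=len(carbons),
        )
    return AlkaneLadder(tuple(int(c) for c in carbons), tuple(times))


def _gen_table(
    rng: np.random.Generator,
    prefix: str,
    n_features: int,
    config: SynthConfig,
    sample_ids: list[str],
    group_of_sample: list[str],
    sample_effects: np.ndarray,
) -> tuple[FeatureTable, dict[str, tuple[str, int, float]], pd.DataFrame]:
    groups = list(config.group_names)
    feature_ids = [f"{prefix}_{i:04d}" for i in range(n_features)]
    is_id = f"{prefix}_IS"

    base = rng.uniform(np.log(1e4), np.log(1e7), size=n_features)
    latent = pd.DataFrame(
        np.tile(base, (len(groups), 1)), index=groups, columns=feature_ids
    )

    n_diff = round(config.frac_differential * n_features)
    planted_idx = rng.choice(n_features, size=n_diff, replace=False)
    planted: dict[str, tuple[str, int, float]] = {}
    for i in sorted(planted_idx):
        g = groups[int(rng.integers(len(groups)))]
        direction = int(rng.choice([-1, 1]))
        latent.loc[g, feature_ids[i]] += direction * np.log(config.effect_size)
        planted[feature_ids[i]] = (g, direction, config.effect_size)

    sigma = np.sqrt(np.log1p(config.cv_noise**2))
    n_samples = len(sample_ids)
    noise = rng.normal(0.0, sigma, size=(n_samples, n_features))
    log_int = (
        sample_effects[:, None]
        + latent.loc[group_of_sample].to_numpy()
        + noise
    )
    values = pd.DataFrame(np.exp(log_int), index=sample_ids, columns=feature_ids)

    # internal standard: shares the sample effect, tight measurement noise
    is_log = sample_effects + np.log(1e6) + rng.normal(0.0, 0.05, size=n_samples)
    values[is_id] = np.exp(is_log)

    table = FeatureTable(
        values=values,
        group_labels=pd.Series(group_of_sample, index=sample_ids),
        internal_standard_id=is_id,
    )
    return table, planted, latent


def inject_missingness(
    table: FeatureTable,
    missing_rate: float,
    lod_quantile: float,
    seed: int,
) -> FeatureTable:
    """Censor below-detection values, then mask cells at random.

    Below-LOD censoring (values under the pooled ``lod_quantile`` of all
    non-internal-standard intensities) runs first; missing-at-random masking
    at ``missing_rate`` runs on top. The internal standard is never touched.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if not 0 <= lod_quantile < 1:
        raise ValueError("lod_quantile must be in [0, 1)")
    if missing_rate == 0 and lod_quantile == 0:
        return table
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    cols = [c for c in values.columns if c != table.internal_standard_id]
    block = values[cols].to_numpy(copy=True)
    if lod_quantile > 0:
        lod = np.nanquantile(block, lod_quantile)
        block[block < lod] = np.nan
    if missing_rate > 0:
        mask = rng.random(block.shape) < missing_rate
        block[mask] = np.nan
    values[cols] = block
    return replace(table, values=values)


def _gen_annotations(
    rng: np.random.Generator,
    voc_ids: list[str],
    is_id: str,
    ladder: AlkaneLadder,
) -> tuple[pd.DataFrame, list[PeakRecord]]:
    n = len(voc_ids)
    classes = [
        str(c)
        for c in rng.choice(
            CHEMICAL_CLASSES, size=n, p=[0.30, 0.16, 0.16, 0.14, 0.10, 0.14]
        )
    ]
    names = [
        _NAME_POOL[i] if i < len(_NAME_POOL) else f"voc compound {i}"
        for i in range(n)
    ]
    t_lo, t_hi = ladder.span
    rts = rng.uniform(t_lo, t_hi, size=n)
    theo_ri = preprocess.compute_ri_many(rts, ladder) + rng.normal(0, 3, size=n)
    ot = np.exp(rng.normal(np.log(0.5), 1.5, size=n))
    # ~8% of compounds lack a published odor threshold
    ot[rng.random(n) < 0.08] = np.nan
    descriptors = [
        sorted(
            str(d)
            for d in rng.choice(
                SENSORY_VOCABULARY, size=int(rng.integers(1, 5)), replace=False
            )
        )
        for _ in range(n)
    ]
    ann = pd.DataFrame(
        {
            "compound_name": names,
            "cas": [f"{rng.integers(50, 99999)}-{rng.integers(10, 99)}-{rng.integers(0, 9)}" for _ in range(n)],
            "chemical_class": classes,
            "theoretical_ri": theo_ri,
            "odor_threshold": ot,
            "descriptors": descriptors,
        },
        index=pd.Index(voc_ids, name="feature_id"),
    )
    # peak QC records: most peaks pass, a realistic minority fails
    sn = np.exp(rng.normal(np.log(300), 1.0, size=n))
    sim = rng.uniform(600, 999, size=n)
    calc_ri = theo_ri + rng.normal(0, 7, size=n)
    far = rng.random(n) < 0.05
    calc_ri[far] += np.where(rng.random(far.sum()) < 0.5, 35.0, -35.0)
    peaks = [
        PeakRecord(
            feature_id=fid,
            signal_to_noise=float(sn[i]),
            similarity=float(sim[i]),
            calculated_ri=float(calc_ri[i]),
        )
        for i, fid in enumerate(voc_ids)
    ]
    peaks.append(PeakRecord(feature_id=is_id, signal_to_noise=1e4, similarity=950.0))
    return validate_annotations(ann), peaks


def _gen_pathways(
    rng: np.random.Generator,
    met_ids: list[str],
    planted: dict[str, tuple[str, int, float]],
    n_pathways: int = 12,
) -> tuple[dict[str, set[str]], dict[str, set[str]], set[str]]:
    planted_ids = sorted(planted)
    other_ids = [f for f in met_ids if f not in planted]
    db: dict[str, set[str]] = {}
    enriched = {"PW01", "PW02"} if planted_ids else set()
    for i in range(1, n_pathways + 1):
        pw = f"PW{i:02d}"
        size = min(int(rng.integers(8, 25)), len(met_ids))
        if pw in enriched and planted_ids:
            k_pl = min(len(planted_ids), max(3, size // 2))
            n_other = min(size - k_pl, len(other_ids))
            members = set(
                rng.choice(planted_ids, size=k_pl, replace=False)
            ) | set(rng.choice(other_ids, size=n_other, replace=False))
        else:
            members = set(rng.choice(other_ids, size=min(size, len(other_ids)), replace=False))
        db[pw] = {str(m) for m in members}
    assignments: dict[str, set[str]] = {}
    for pw, members in db.items():
        for f in members:
            assignments.setdefault(f, set()).add(pw)
    return db, assignments, enriched


def generate_study(config: SynthConfig = SynthConfig()) -> SynthStudy:
    """Generate a complete synthetic study from one seeded generator.

    Returns feature tables for metabolites and VOCs (with missingness
    injected), VOC annotations, the alkane ladder, a pathway database, VOC
    peak-QC records, and the ground-truth record. Identical configs yield
    byte-identical studies.
    """
    rng = np.random.default_rng(config.seed)
    groups = list(config.group_names)
    sample_ids = [
        f"{g}_{r + 1}" for g in groups for r in range(config.n_per_group)
    ]
    group_of_sample = [g for g in groups for _ in range(config.n_per_group)]
    sample_effects = rng.normal(0.0, 0.15, size=len(sample_ids))

    mets, met_planted, met_latent = _gen_table(
        rng, "MET", config.n_metabolites, config, sample_ids, group_of_sample,
        sample_effects,
    )
    vocs, voc_planted, voc_latent = _gen_table(
        rng, "VOC", config.n_vocs, config, sample_ids, group_of_sample,
        sample_effects,
    )

    ladder = make_ladder(rng=rng)
    annotations, voc_peaks = _gen_annotations(
        rng, [f for f in vocs.feature_ids if f != vocs.internal_standard_id],
        vocs.internal_standard_id, ladder,
    )
    pathways, assignments, enriched = _gen_pathways(
        rng, [f for f in mets.feature_ids if f != mets.internal_standard_id],
        met_planted,
    )

    miss_seed = int(rng.integers(2**31))
    mets = inject_missingness(
        mets, config.missing_rate, config.lod_quantile, miss_seed
    )
    vocs = inject_missingness(
        vocs, config.missing_rate, config.lod_quantile, miss_seed + 1
    )

    truth = TruthRecord(
        planted={"metabolite": met_planted, "voc": voc_planted},
        latent_means={"metabolite": met_latent, "voc": voc_latent},
        pathway_assignments=assignments,
        enriched_pathways=enriched,
    )
    return SynthStudy(
        metabolites=mets,
        vocs=vocs,
        annotations=annotations,
        ladder=ladder,
        pathways=pathways,
        voc_peaks=voc_peaks,
        truth=truth,
        config=config,
    )


def write_study(study: SynthStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every study table as CSV plus a JSON truth/config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metabolites": write_feature_table(study.metabolites, outdir / "metabolites.csv"),
        "vocs": write_feature_table(study.vocs, outdir / "vocs.csv"),
        "annotations": write_annotations(study.annotations, outdir / "voc_annotations.csv"),
        "ladder": write_ladder(study.ladder, outdir / "alkane_ladder.csv"),
        "pathways": write_pathways(study.pathways, outdir / "pathways.csv"),
        "voc_peaks": write_peak_records(study.voc_peaks, outdir / "voc_peaks.csv"),
    }
    truth_json = {
        "schema": "flavoromics/1",
        "config": asdict(study.config),
        "planted": {
            tbl: {f: list(v) for f, v in sorted(d.items())}
            for tbl, d in study.truth.planted.items()
        },
        "enriched_pathways": sorted(study.truth.enriched_pathways),
        "pathway_assignments": {
            f: sorted(p) for f, p in sorted(study.truth.pathway_assignments.items())
        },
    }
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["truth"] = truth_path
    return paths
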