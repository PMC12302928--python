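"""End-to-end orchestration: simulate -> preprocess -> models -> reports.

A run is a pure function of (inputs, config, seed). Every stage writes its
outputs as CSV/JSON under the run directory, and the final manifest records
the config echo, per-stage record counts and a SHA-256 checksum of every
file — so two runs with the same config are byte-identical and trivially
diffable. No timestamps or absolute paths enter any output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, chemometrics, diffscreen, flavor, preprocess, synthgen, tables_io
from .preprocess import QcThresholds
from .synthgen import SynthConfig

MANIFEST_SCHEMA = "flavoromics/manifest/1"


@dataclass
class RunConfig:
    """Everything a pipeline run needs; echoed verbatim into the manifest."""

    output_dir: Path
    simulate: bool = True
    input_dir: Path | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    n_ortho: int = 1
    cv: str | int = "loo"
    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    use_adjusted: bool = False
    roav_agg: str = "mean"
    top_k_attributes: int = 10
    missing_filter_metabolites: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)
        if not self.simulate and self.input_dir is None:
            raise ValueError("input_dir is required when simulate is off")
        if self.roav_agg not in ("mean", "median"):
            raise ValueError("roav_agg must be 'mean' or 'median'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "synth" in raw and isinstance(raw["synth"], dict):
            raw["synth"] = SynthConfig(**raw["synth"])
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QcThresholds(**raw["qc"])
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        # paths are run-location metadata, not analysis parameters; keeping
        # them out makes equal configs give byte-identical manifests
        d.pop("output_dir")
        d.pop("input_dir")
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _count_rows(path: Path) -> int | None:
    if path.suffix != ".csv":
        return None
    with open(path) as fh:
        return sum(
            1 for line in fh if line.strip() and not line.startswith("#")
        ) - 1  # header


def _write_csv(frame: pd.DataFrame, path: Path, index_label: str) -> Path:
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: {tables_io.SCHEMA_VERSION}\n")
        frame.to_csv(fh, index_label=index_label)
    return path


def _write_json(obj: dict, path: Path) -> Path:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def _load_inputs(indir: Path) -> synthgen.SynthStudy | dict:
    names = {
        "metabolites": "metabolites.csv",
        "vocs": "vocs.csv",
        "annotations": "voc_annotations.csv",
        "ladder": "alkane_ladder.csv",
        "pathways": "pathways.csv",
        "voc_peaks": "voc_peaks.csv",
    }
    for key, fname in names.items():
        if not (indir / fname).exists():
            raise FileNotFoundError(f"missing input file: {indir / fname}")
    return {
        "metabolites": tables_io.read_feature_table(indir / names["metabolites"]),
        "vocs": tables_io.read_feature_table(indir / names["vocs"]),
        "annotations": tables_io.read_annotations(indir / names["annotations"]),
        "ladder": tables_io.read_ladder(indir / names["ladder"]),
        "pathways": tables_io.read_pathways(indir / names["pathways"]),
        "voc_peaks": tables_io.read_peak_records(indir / names["voc_peaks"]),
    }


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    outputs: list[Path] = []

    def record(stage: str, paths: list[Path], counts: dict | None = None) -> None:
        stages.append(
            {
                "name": stage,
                "outputs": {
                    str(p.relative_to(out)): {
                        "sha256": _sha256(p),
                        "n_rows": _count_rows(p),
                    }
                    for p in sorted(paths)
                },
                **({"counts": counts} if counts else {}),
            }
        )
        outputs.extend(paths)

    # -- stage 1: inputs ---------------------------------------------------
    if config.simulate:
        cfg = dataclasses.replace(config.synth, seed=config.seed)
        study = synthgen.generate_study(cfg)
        input_dir = out / "inputs"
        paths = synthgen.write_study(study, input_dir)
        record("simulate", list(paths.values()))
        inputs = {
            "metabolites": study.metabolites,
            "vocs": study.vocs,
            "annotations": study.annotations,
            "ladder": study.ladder,
            "pathways": study.pathways,
            "voc_peaks": study.voc_peaks,
        }
    else:
        inputs = _load_inputs(config.input_dir)
        record("load_inputs", [])

    # -- stage 2: preprocess ----------------------------------------------
    pre_dir = out / "preprocess"
    pre_dir.mkdir(exist_ok=True)
    mets, met_log = preprocess.preprocess_table(
        inputs["metabolites"],
        thresholds=config.qc,
        apply_missing_filter=config.missing_filter_metabolites,
    )
    vocs, voc_log = preprocess.preprocess_table(
        inputs["vocs"],
        thresholds=config.qc,
        peaks=inputs["voc_peaks"],
        annotations=inputs["annotations"],
    )
    p1 = tables_io.write_feature_table(mets, pre_dir / "metabolites_processed.csv")
    p2 = tables_io.write_feature_table(vocs, pre_dir / "vocs_processed.csv")
    qc_report = voc_log.get("qc_report", pd.DataFrame())
    p3 = _write_csv(qc_report.set_index("feature_id") if len(qc_report) else qc_report,
                    pre_dir / "voc_qc_rejections.csv", "feature_id")
    record(
        "preprocess",
        [p1, p1.with_suffix(".meta.json"), p2, p2.with_suffix(".meta.json"), p3],
        counts={
            "metabolites_removed": len(met_log.get("missingness_removed", [])),
            "vocs_qc_removed": len(voc_log.get("qc_removed", [])),
            "vocs_missingness_removed": len(voc_log.get("missingness_removed", [])),
            "metabolites_out": mets.n_features,
            "vocs_out": vocs.n_features,
        },
    )

    pairs = list(itertools.combinations(mets.groups, 2))

    # -- stage 3: chemometrics --------------------------------------------
    chem_dir = out / "chemometrics"
    chem_dir.mkdir(exist_ok=True)
    chem_paths: list[Path] = []
    summary: dict = {"pca": {}, "oplsda": {}}
    for name, table in (("metabolites", mets), ("vocs", vocs)):
        X = chemometrics.log_intensities(table)
        pca = chemometrics.fit_pca(X, k=2)
        summary["pca"][name] = {
            "explained_pc1": float(pca.explained_variance_fraction[0]),
            "explained_pc2": float(pca.explained_variance_fraction[1]),
        }
        chem_paths.append(
            _write_csv(pca.scores, chem_dir / f"{name}_pca_scores.csv", "sample_id")
        )
        for g1, g2 in pairs:
            sub = table.subset_groups((g1, g2))
            model = chemometrics.fit_oplsda(
                chemometrics.log_intensities(sub),
                list(sub.group_labels),
                n_ortho=config.n_ortho,
                cv=config.cv,
                cv_seed=config.seed,
            )
            summary["oplsda"][f"{name}:{g1}_vs_{g2}"] = {
                "r2y": model.r2y,
                "q2": model.q2,
            }
    chem_paths.append(_write_json(summary, chem_dir / "model_summary.json"))
    record("chemometrics", chem_paths)

    # -- stage 4: differential screening ----------------------------------
    diff_dir = out / "diff"
    diff_dir.mkdir(exist_ok=True)
    diff_paths: list[Path] = []
    diff_counts: dict = {}
    selected: dict[str, dict[tuple[str, str], list[str]]] = {
        "metabolites": {}, "vocs": {}
    }
    for name, table in (("metabolites", mets), ("vocs", vocs)):
        for g1, g2 in pairs:
            res = diffscreen.differential_analysis(
                table,
                (g1, g2),
                n_ortho=config.n_ortho,
                vip_threshold=config.vip_threshold,
                p_threshold=config.p_threshold,
                use_adjusted=config.use_adjusted,
            )
            tag = f"{name}_{g1}_vs_{g2}"
            diff_paths.append(
                _write_csv(res.frame, diff_dir / f"{tag}.csv", "feature_id")
            )
            diff_counts[tag] = res.summary()
            selected[name][(g1, g2)] = res.selected_features
    diff_paths.append(_write_json(diff_counts, diff_dir / "summary.json"))
    record("diff", diff_paths, counts={
        k: v["n_selected"] for k, v in diff_counts.items()
    })

    # -- stage 5: ROAV ------------------------------------------------------
    roav_dir = out / "roav"
    roav_dir.mkdir(exist_ok=True)
    roav_paths = []
    roav_tables = flavor.roav_by_group(vocs, inputs["annotations"], agg=config.roav_agg)
    for g in sorted(roav_tables):
        roav_paths.append(
            _write_csv(roav_tables[g], roav_dir / f"roav_{g}.csv", "feature_id")
        )
    comp = flavor.class_composition(vocs, inputs["annotations"])
    roav_paths.append(_write_csv(comp, roav_dir / "class_composition.csv", "group"))
    venn = flavor.venn_partition(flavor.presence_by_group(inputs["vocs"]))
    venn_json = {
        "+".join(k): sorted(v) for k, v in venn.items()
    }
    roav_paths.append(
        _write_json({"regions": {k: len(v) for k, v in venn_json.items()},
                     "members": venn_json}, roav_dir / "venn.json")
    )
    record("roav", roav_paths)

    # -- stage 6: sensory network ------------------------------------------
    net_dir = out / "network"
    net_dir.mkdir(exist_ok=True)
    voc_union = sorted({f for sel in selected["vocs"].values() for f in sel})
    graph = flavor.build_sensory_network(
        voc_union, inputs["annotations"], top_k=config.top_k_attributes
    )
    edge_rows = [
        (u, v) if graph.nodes[u]["kind"] == "voc" else (v, u)
        for u, v in graph.edges
    ]
    edges = pd.DataFrame(sorted(edge_rows), columns=["voc", "attribute"])
    net_paths = [
        _write_csv(edges.set_index("voc") if len(edges) else edges,
                   net_dir / "edges.csv", "voc"),
        _write_json(
            {
                n: {"kind": graph.nodes[n]["kind"], "degree": graph.nodes[n]["degree"]}
                for n in sorted(graph.nodes)
            },
            net_dir / "nodes.json",
        ),
    ]
    record("network", net_paths, counts={"n_edges": int(graph.number_of_edges())})

    # -- stage 7: correlation ----------------------------------------------
    corr_dir = out / "correlate"
    corr_dir.mkdir(exist_ok=True)
    met_union = sorted({f for sel in selected["metabolites"].values() for f in sel})
    corr_paths = []
    if met_union and voc_union:
        corr = assoc.spearman_matrix(
            chemometrics.log_intensities(mets)[met_union],
            chemometrics.log_intensities(vocs)[voc_union],
        )
        corr_paths.append(_write_csv(corr.rho, corr_dir / "rho.csv", "metabolite"))
        corr_paths.append(_write_csv(corr.p, corr_dir / "p.csv", "metabolite"))
        long = corr.to_long()
        corr_paths.append(
            _write_csv(long.set_index("metabolite"), corr_dir / "edges.csv",
                       "metabolite")
        )
        n_sig = int(corr.significant.to_numpy().sum())
    else:
        corr_paths.append(
            _write_csv(pd.DataFrame(), corr_dir / "rho.csv", "metabolite")
        )
        n_sig = 0
    record("correlate", corr_paths, counts={"n_significant": n_sig})

    # -- stage 8: enrichment -----------------------------------------------
    enrich_dir = out / "enrich"
    enrich_dir.mkdir(exist_ok=True)
    universe = set(mets.feature_ids)
    enr = assoc.ora_hypergeometric(
        set(met_union) & universe, inputs["pathways"], universe
    )
    enrich_paths = [_write_csv(enr, enrich_dir / "enrichment.csv", "pathway_id")]
    record("enrich", enrich_paths, counts={
        "n_significant": int((enr["p_adjusted"] < 0.05).sum())
    })

    manifest = {
        "schema": MANIFEST_SCHEMA,
        "seed": config.seed,
        "config": config.echo(),
        "stage_order": [s["name"] for s in stages],
        "stages": stages,
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
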