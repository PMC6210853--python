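"""End-to-end pipeline: simulate -> call features -> classify -> score -> stats.

Every stage is a pure function of its inputs and the :class:`AnalysisConfig`;
outputs carry the config hash in a leading comment line, and a manifest
records versions, the config, and per-stage row counts, so a rerun with the
same inputs and config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, read_cohort, write_feature_table
from .features import (
    ZScoreCalibration,
    binarize_cn_fraction,
    call_features,
    cn_alteration_fraction,
)
from .cohort import read_maf_mutations
from .scoring import score_cohort
from .simulate import GeneratorConfig, write_simulation
from .stats import association_scan, km_estimate, logrank_test
from .subclasses import MolecularSubclassifier

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All analysis thresholds; defaults are the published constants."""

    afp_cut: float = 200.0                 # ng/mL
    fal_threshold: float | str = "median"  # percent, or "median" for the cohort median
    min_informative: int = 10
    hypo_mode: str = "cluster"             # "cluster" | "zscore"
    calibration: dict | None = None        # mean/sd/threshold for hypo_mode="zscore"
    cn_threshold: float = 39.0             # percent altered genes = high-FAL surrogate
    log_ratio_cut: float = 0.2
    aggressive_min_four: int = 3
    aggressive_min_three: int = 2
    cluster_method: str = "ward"
    cluster_metric: str = "euclidean"
    n_subclasses: int = 4
    seed: int = 0
    sim_n: int = 125

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def zscore_calibration(self) -> ZScoreCalibration | None:
        if self.calibration is None:
            return None
        return ZScoreCalibration(**self.calibration)


def _write_with_header(df: pd.DataFrame, path: Path, config: AnalysisConfig,
                       index: bool = True, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# hccmolrisk={__version__} config_hash={config.digest()}\n")
        df.to_csv(fh, sep="\t", index=index, **kwargs)


def run_pipeline(config: AnalysisConfig, out_dir: str | Path,
                 cohort_dir: str | Path | None = None) -> dict:
    """Run all stages; returns the manifest (also written to out_dir/manifest.json).

    When ``cohort_dir`` is None a cohort of ``config.sim_n`` samples is
    simulated under ``config.seed`` into ``out_dir/cohort``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config.to_dict(),
                      "config_hash": config.digest(), "stages": {}}

    if cohort_dir is None:
        cohort_dir = out_dir / "cohort"
        sim = GeneratorConfig(n=config.sim_n, seed=config.seed)
        cohort, _ = write_simulation(sim, cohort_dir)
        manifest["stages"]["simulate"] = {"rows": cohort.n_samples}
    else:
        cohort = read_cohort(cohort_dir)
    manifest["cohort_dir"] = str(cohort_dir)

    features = call_features(
        cohort,
        mode=config.hypo_mode,
        calibration=config.zscore_calibration(),
        fal_threshold=config.fal_threshold,
        min_informative=config.min_informative,
        method=config.cluster_method,
        metric=config.cluster_metric,
    )
    write_feature_table(features, out_dir / "feature_table.tsv")
    manifest["stages"]["call_features"] = {
        "rows": len(features),
        "fal_threshold": features.attrs["fal_threshold"],
    }

    scorable = features.dropna(subset=["fal_percent"])
    clf = MolecularSubclassifier(
        n_clusters=config.n_subclasses,
        method=config.cluster_method, metric=config.cluster_metric,
    ).fit(scorable)
    _write_with_header(clf.assignments_, out_dir / "subclasses.tsv", config,
                       float_format="%.6f")
    manifest["stages"]["classify"] = {
        "rows": len(clf.assignments_),
        "subclass_sizes": clf.assignments_["subclass"].value_counts().to_dict(),
    }

    scores = score_cohort(scorable, mode="four_factor",
                          aggressive_min=config.aggressive_min_four)
    _write_with_header(scores, out_dir / "scores.tsv", config)
    manifest["stages"]["score"] = {
        "rows": len(scores),
        "patterns": scores["pattern"].value_counts().to_dict(),
    }

    assoc_features = scorable[["ctnnb1_mut", "tp53_mut", "tertp_mut",
                               "tsg_hyper", "global_hypo", "fal_high"]].copy()
    assoc_features["subclass"] = clf.assignments_["subclass"]
    assoc = association_scan(cohort.clinical.loc[scorable.index], assoc_features,
                             afp_cut=config.afp_cut)
    assoc_table = pd.DataFrame([
        {"feature": a.feature, "covariate": a.covariate,
         "statistic": a.test.statistic, "df": a.test.df, "p_value": a.test.p_value}
        for a in assoc
    ])
    _write_with_header(assoc_table, out_dir / "associations.tsv", config,
                       index=False, float_format="%.6g")
    manifest["stages"]["associations"] = {"rows": len(assoc_table)}

    clin = cohort.clinical.loc[scorable.index]
    km_rows = []
    for pattern in ("aggressive", "mild"):
        ids = scores.index[scores["pattern"] == pattern]
        if len(ids) == 0:
            continue
        curve = km_estimate(clin.loc[ids, "rfs_months"],
                            clin.loc[ids, "recurrence_event"])
        for t, s, r in zip(curve.event_times, curve.survival_probabilities,
                           curve.numbers_at_risk):
            km_rows.append({"group": pattern, "time": t, "survival": s, "at_risk": r})
    km_table = pd.DataFrame(km_rows, columns=["group", "time", "survival", "at_risk"])
    _write_with_header(km_table, out_dir / "km.tsv", config, index=False,
                       float_format="%.6f")
    surv_stage: dict = {"rows": len(km_table)}
    agg = scores.index[scores["pattern"] == "aggressive"]
    mild = scores.index[scores["pattern"] == "mild"]
    if len(agg) and len(mild):
        try:
            lr = logrank_test(clin.loc[agg, "rfs_months"], clin.loc[agg, "recurrence_event"],
                              clin.loc[mild, "rfs_months"], clin.loc[mild, "recurrence_event"])
            surv_stage["logrank_p"] = lr.p_value
            surv_stage["logrank_statistic"] = lr.statistic
        except ValueError as exc:
            surv_stage["logrank_error"] = str(exc)
    manifest["stages"]["survival"] = surv_stage

    # hash covers config + stage outcomes, not filesystem paths
    hashed = {"config": manifest["config"], "stages": manifest["stages"]}
    manifest_blob = json.dumps(hashed, sort_keys=True, indent=2, default=str)
    manifest["manifest_hash"] = hashlib.sha256(manifest_blob.encode()).hexdigest()[:16]
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2, default=str))
    return manifest


def score_tcga(cn_path: str | Path, maf_path: str | Path, survival_path: str | Path,
               out_dir: str | Path, config: AnalysisConfig | None = None) -> dict:
    """Three-factor scoring of an array cohort (copy-number surrogate for FAL).

    Reads a gene x sample thresholded copy-number table, a MAF subset and a
    survival table; scores each sample on {CTNNB1 wild-type, TP53 mutant,
    copy-number-alteration fraction >= threshold} with aggressive = count
    >= 2, and compares recurrence-free survival between patterns by
    log-rank test.
    """
    from .cohort import GeneCopyNumberMatrix

    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cn_frame = pd.read_csv(cn_path, sep="\t", index_col="gene_id")
    cn = GeneCopyNumberMatrix(cn_frame, value_kind="thresholded")
    survival = pd.read_csv(survival_path, sep="\t").set_index("sample_id")
    samples = list(cn.sample_ids)
    flags = read_maf_mutations(maf_path, sample_ids=samples)

    features = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    features["ctnnb1_mut"] = flags["ctnnb1_mut"]
    features["tp53_mut"] = flags["tp53_mut"]
    fractions = pd.Series(
        {s: cn_alteration_fraction(cn, s, log_ratio_cut=config.log_ratio_cut)
         for s in samples}, name="cn_fraction")
    features["fal_high"] = [
        binarize_cn_fraction(f, threshold=config.cn_threshold) for f in fractions]
    scores = score_cohort(features, mode="three_factor",
                          aggressive_min=config.aggressive_min_three)
    scores["cn_fraction"] = fractions
    scores["fal_provenance"] = "copy_number_fraction"
    _write_with_header(scores, out_dir / "tcga_scores.tsv", config,
                       float_format="%.4f")

    result: dict = {"n": len(scores),
                    "patterns": scores["pattern"].value_counts().to_dict()}
    agg = scores.index[scores["pattern"] == "aggressive"]
    mild = scores.index[scores["pattern"] == "mild"]
    if len(agg) and len(mild):
        lr = logrank_test(
            survival.loc[agg, "rfs_months"], survival.loc[agg, "recurrence_event"],
            survival.loc[mild, "rfs_months"], survival.loc[mild, "recurrence_event"])
        result["logrank_p"] = lr.p_value
        result["logrank_statistic"] = lr.statistic
    (out_dir / "tcga_result.json").write_text(json.dumps(result, indent=2, default=str))
    return result
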