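"""Synthetic cohorts with the statistical structure the analysis assumes.

Each sample is drawn from one of the four molecular subclasses (A1, A2,
B1, B2 at the reference cohort's proportions); the six molecular events
and the subclass-structured clinical covariates are conditionally
independent Bernoulli draws given the subclass, at the reference
per-subclass prevalences.  Measurements are then emitted consistently
with the drawn truth: promoter methylation from a high- or low-mean Beta
depending on the hypermethylation flag (per-marker means roughly matching
the reference cohort's medians), repeat-element methylation analogously
for global hypomethylation, microsatellite imbalance as Bernoulli draws
at a per-sample target FAL drawn from a high or low mixture component,
and recurrence times from an exponential hazard that multiplies by a
fixed ratio per molecular risk factor, censored uniformly.

Every sample has its own RNG substream keyed by (seed, sample index), so
output is byte-identical across runs and stable under changes of n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    GeneCopyNumberMatrix,
    PROMOTER_MARKERS,
    REPEAT_MARKERS,
    write_cohort,
)

SUBCLASS_ORDER = ("A1", "A2", "B1", "B2")

# Reference per-subclass prevalences of the six molecular events
# (subclass sizes 27, 21, 41, 36 of 125).
DEFAULT_EVENT_PREVALENCE: dict[str, tuple[float, float, float, float]] = {
    "ctnnb1_mut": (1 / 27, 0 / 21, 13 / 41, 17 / 36),
    "tp53_mut": (3 / 27, 0 / 21, 23 / 41, 1 / 36),
    "tertp_mut": (5 / 27, 15 / 21, 31 / 41, 34 / 36),
    "tsg_hyper": (6 / 27, 2 / 21, 39 / 41, 34 / 36),
    "global_hypo": (16 / 27, 2 / 21, 38 / 41, 11 / 36),
    "fal_high": (19 / 27, 3 / 21, 37 / 41, 8 / 36),
}

# Subclass-structured clinical covariates (vascular invasion has 2 missing
# in the reference tables, hence the 39-denominator for B1).
DEFAULT_COVARIATE_PREVALENCE: dict[str, tuple[float, float, float, float]] = {
    "hcv": (10 / 27, 15 / 21, 25 / 41, 27 / 36),
    "hbv": (10 / 27, 2 / 21, 12 / 41, 5 / 36),
    "afp_high": (14 / 27, 4 / 21, 23 / 41, 5 / 36),
    "vascular_invasion": (17 / 27, 5 / 21, 25 / 39, 11 / 36),
    "mod_poor_diff": (22 / 27, 12 / 20, 31 / 39, 21 / 36),
}

# Beta-component means (altered state, normal state) per methylation marker,
# chosen so cohort-marginal medians roughly match the reference cohort's
# printed medians while keeping the two components >= 4 sd apart at the
# default concentration.
DEFAULT_PROMOTER_MEANS: dict[str, tuple[float, float]] = {
    "APC": (0.60, 0.30), "CDKN2A": (0.32, 0.06), "RASSF1A": (0.48, 0.20),
    "HIC1": (0.38, 0.12), "GSTP1": (0.50, 0.18), "RUNX3": (0.16, 0.02),
    "SOCS1": (0.46, 0.18), "PRDM2": (0.22, 0.04),
}
DEFAULT_REPEAT_MEANS: dict[str, tuple[float, float]] = {
    # (hypomethylated mean, normal mean)
    "Alu": (0.22, 0.42), "LINE1": (0.18, 0.40), "SAT2": (0.22, 0.50),
}


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


@dataclass
class GeneratorConfig:
    """Study conditions of the simulated cohort; defaults are the reference cohort's."""

    n: int = 125
    seed: int = 0
    subclass_proportions: tuple[float, float, float, float] = (
        27 / 125, 21 / 125, 41 / 125, 36 / 125)
    event_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_PREVALENCE))
    covariate_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCE))
    promoter_means: dict = field(default_factory=lambda: dict(DEFAULT_PROMOTER_MEANS))
    repeat_means: dict = field(default_factory=lambda: dict(DEFAULT_REPEAT_MEANS))
    beta_concentration: float = 130.0
    panel_size: int = 400
    informative_rate: float = 0.30
    fal_low_mean: float = 0.055          # target FAL, chromosomally stable component
    fal_high_mean: float = 0.32          # unstable component; cohort median lands a little
    fal_concentration: float = 110.0     # above the reference cohort's 21%
    baseline_hazard: float = 0.002       # recurrence events per month at zero risk factors
    hr_per_factor: float = 2.2           # hazard ratio per molecular risk factor
    censor_window: float = 106.0         # uniform censoring horizon, months
    afp_cut: float = 200.0               # ng/mL, AFP dichotomization

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if abs(sum(self.subclass_proportions) - 1.0) > 1e-9:
            raise ValueError("subclass proportions must sum to 1")
        for name, probs in list(self.event_prevalence.items()) + list(
                self.covariate_prevalence.items()):
            if len(probs) != 4 or any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"bad prevalence vector for {name!r}")
        if not self.hr_per_factor > 0:
            raise ValueError("hazard ratio must be > 0")
        if not 0.0 <= self.informative_rate <= 1.0:
            raise ValueError("informative_rate must be in [0, 1]")

    def marginal_prevalence(self, event: str) -> float:
        """Cohort-marginal prevalence implied by subclass mixing."""
        probs = self.event_prevalence[event]
        return float(sum(w * p for w, p in zip(self.subclass_proportions, probs)))


@dataclass
class GroundTruth:
    """True per-sample subclass, events and four-factor risk count."""

    table: pd.DataFrame  # indexed by sample_id

    def write(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t").set_index("sample_id")
        for col in df.columns:
            if col.startswith(("ctnnb1", "tp53", "tertp", "tsg", "global", "fal_h")):
                df[col] = df[col].astype(bool)
        return cls(df)


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a full cohort plus its ground truth (in memory; see :func:`write_simulation`)."""
    n = config.n
    kappa = config.beta_concentration
    clin_rows, mut_rows, meth_rows, ms_frames, truth_rows = [], [], [], [], []
    for i in range(n):
        rng = _sample_rng(config.seed, i)
        sid = f"S{i + 1:05d}"
        sub = int(rng.choice(4, p=config.subclass_proportions))

        events = {ev: bool(rng.random() < config.event_prevalence[ev][sub])
                  for ev in DEFAULT_EVENT_PREVALENCE}
        cov = {cv: bool(rng.random() < config.covariate_prevalence[cv][sub])
               for cv in DEFAULT_COVARIATE_PREVALENCE}

        sex = "male" if rng.random() < 90 / 125 else "female"
        age = float(np.clip(rng.normal(63.0, 9.0), 25.0, 90.0))
        size = float(np.clip(rng.lognormal(np.log(3.6), 0.5), 0.5, 20.0))
        multiple = bool(rng.random() < 58 / 113)
        if cov["afp_high"]:
            afp = float(config.afp_cut + rng.exponential(300.0))
        else:
            afp = float(rng.uniform(1.0, config.afp_cut - 1.0))

        meth = {"sample_id": sid}
        for marker in PROMOTER_MARKERS:
            hi, lo = config.promoter_means[marker]
            mean = hi if events["tsg_hyper"] else lo
            a, b = _beta_params(mean, kappa)
            meth[marker] = float(rng.beta(a, b))
        for marker in REPEAT_MARKERS:
            hypo, normal = config.repeat_means[marker]
            mean = hypo if events["global_hypo"] else normal
            a, b = _beta_params(mean, kappa)
            meth[marker] = float(rng.beta(a, b))

        target_mean = config.fal_high_mean if events["fal_high"] else config.fal_low_mean
        a, b = _beta_params(target_mean, config.fal_concentration)
        target_fal = float(rng.beta(a, b))
        informative = rng.random(config.panel_size) < config.informative_rate
        imbalance = informative & (rng.random(config.panel_size) < target_fal)

        risk_count = int((not events["ctnnb1_mut"]) + events["tp53_mut"]
                         + events["fal_high"] + events["global_hypo"])
        hazard = config.baseline_hazard * config.hr_per_factor ** risk_count
        t_event = float(rng.exponential(1.0 / hazard))
        t_censor = float(rng.uniform(0.0, config.censor_window))
        rfs = min(t_event, t_censor)
        event = int(t_event <= t_censor)

        clin_rows.append({
            "sample_id": sid, "sex": sex, "age_years": round(age, 1),
            "hbsag": "positive" if cov["hbv"] else "negative",
            "hcvab": "positive" if cov["hcv"] else "negative",
            "afp_ng_ml": round(afp, 1), "tumor_size_cm": round(size, 2),
            "vascular_invasion": "presence" if cov["vascular_invasion"] else "absence",
            "tumor_number": "multiple" if multiple else "solitary",
            "differentiation": "moderately_poorly" if cov["mod_poor_diff"] else "well",
            "treatment": "resection",
            "rfs_months": round(rfs, 3), "recurrence_event": event,
        })
        mut_rows.append({"sample_id": sid,
                         "ctnnb1_mut": events["ctnnb1_mut"],
                         "tp53_mut": events["tp53_mut"],
                         "tertp_mut": events["tertp_mut"]})
        meth_rows.append(meth)
        ms_frames.append(pd.DataFrame({
            "sample_id": sid,
            "locus_id": [f"L{j + 1:03d}" for j in range(config.panel_size)],
            "informative": informative,
            "imbalance": imbalance,
        }))
        truth_rows.append({"sample_id": sid, "subclass": SUBCLASS_ORDER[sub],
                           **events, "target_fal": target_fal,
                           "risk_count": risk_count})

    clin_cols = ["sample_id", "sex", "age_years", "hbsag", "hcvab", "afp_ng_ml",
                 "tumor_size_cm", "vascular_invasion", "tumor_number",
                 "differentiation", "treatment", "rfs_months", "recurrence_event"]
    clinical = pd.DataFrame(clin_rows, columns=clin_cols).set_index("sample_id")
    mutations = pd.DataFrame(
        mut_rows, columns=["sample_id", "ctnnb1_mut", "tp53_mut", "tertp_mut"],
    ).astype({c: bool for c in ("ctnnb1_mut", "tp53_mut", "tertp_mut")}
             ).set_index("sample_id")
    methylation = pd.DataFrame(
        meth_rows, columns=["sample_id"] + list(PROMOTER_MARKERS + REPEAT_MARKERS),
    ).set_index("sample_id").astype(float)
    if ms_frames:
        micro = pd.concat(ms_frames, ignore_index=True)
    else:
        micro = pd.DataFrame(columns=["sample_id", "locus_id", "informative", "imbalance"])
        micro = micro.astype({"informative": bool, "imbalance": bool})
    cohort = Cohort(clinical=clinical, mutations=mutations, methylation=methylation,
                    microsatellites=micro,
                    provenance=f"simulated, seed={config.seed}, n={n}")
    truth_cols = ["sample_id", "subclass"] + list(DEFAULT_EVENT_PREVALENCE) + [
        "target_fal", "risk_count"]
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    truth = truth.set_index("sample_id")
    return cohort, GroundTruth(truth)


def write_simulation(config: GeneratorConfig, directory: str | Path) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and write all cohort tables plus ground_truth.tsv."""
    cohort, truth = generate_cohort(config)
    directory = Path(directory)
    write_cohort(cohort, directory)
    truth.write(directory / "ground_truth.tsv")
    return cohort, truth


# ---------------------------------------------------------------------------
# Array-cohort fixture: copy-number matrix + MAF + survival table
# ---------------------------------------------------------------------------

@dataclass
class TCGAFixtureConfig:
    """Conditions for the array-style validation fixture (three-factor mode)."""

    n: int = 168
    seed: int = 0
    gene_count: int = 1000
    cn_low_mean: float = 0.20       # altered-gene fraction, low-instability component
    cn_high_mean: float = 0.55      # high-instability component
    cn_concentration: float = 80.0
    cn_high_prob: float = 0.5
    ctnnb1_prev: float = 0.25
    tp53_prev: float = 0.30
    tertp_prev: float = 0.60
    baseline_hazard: float = 0.004
    hr_per_factor: float = 2.2
    censor_window: float = 120.0

    def __post_init__(self) -> None:
        if self.n < 0 or self.gene_count <= 0:
            raise ValueError("n and gene_count must be positive")
        for p in (self.cn_high_prob, self.ctnnb1_prev, self.tp53_prev, self.tertp_prev):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class TCGAFixture:
    copynumber: GeneCopyNumberMatrix
    maf: pd.DataFrame
    survival: pd.DataFrame       # sample_id, rfs_months, recurrence_event
    ground_truth: pd.DataFrame   # sample_id, flags, cn_fraction, risk_count

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cn = self.copynumber.values.copy()
        cn.index.name = "gene_id"
        cn.to_csv(directory / "copynumber.tsv", sep="\t")
        self.maf.to_csv(directory / "mutations.maf", sep="\t", index=False)
        self.survival.to_csv(directory / "survival.tsv", sep="\t", index=False,
                             float_format="%.3f")
        self.ground_truth.to_csv(directory / "ground_truth.tsv", sep="\t", index=False,
                                 float_format="%.6f")


# MAF coordinates drawn inside the GRCh37 regions the MAF reader filters on
_MAF_SITES = {
    "ctnnb1": ("CTNNB1", "3", 41_266_100, "Missense_Mutation"),
    "tp53": ("TP53", "17", 7_578_000, "Missense_Mutation"),
    "tertp": ("TERT", "5", 1_295_228, "5'Flank"),
}


def generate_tcga_fixture(config: TCGAFixtureConfig) -> TCGAFixture:
    """Array-style cohort: thresholded copy-number states, MAF calls, survival."""
    maf_rows, truth_rows, surv_rows = [], [], []
    cn_cols: dict[str, np.ndarray] = {}
    genes = [f"G{j + 1:05d}" for j in range(config.gene_count)]
    for i in range(config.n):
        rng = _sample_rng(config.seed, i)
        sid = f"T{i + 1:05d}"
        high_cn = bool(rng.random() < config.cn_high_prob)
        mean = config.cn_high_mean if high_cn else config.cn_low_mean
        a, b = _beta_params(mean, config.cn_concentration)
        frac = float(rng.beta(a, b))
        n_alt = int(round(frac * config.gene_count))
        states = np.zeros(config.gene_count, dtype=int)
        if n_alt:
            idx = rng.choice(config.gene_count, size=n_alt, replace=False)
            states[idx] = rng.choice([-2, -1, 1, 2], size=n_alt)
        cn_cols[sid] = states

        flags = {
            "ctnnb1": bool(rng.random() < config.ctnnb1_prev),
            "tp53": bool(rng.random() < config.tp53_prev),
            "tertp": bool(rng.random() < config.tertp_prev),
        }
        for key, present in flags.items():
            if present:
                gene, chrom, pos, vclass = _MAF_SITES[key]
                maf_rows.append({
                    "Hugo_Symbol": gene, "Chromosome": chrom, "Start_Position": pos,
                    "Variant_Classification": vclass, "Tumor_Sample_Barcode": sid,
                })

        cn_fraction = 100.0 * (states != 0).sum() / config.gene_count
        risk_count = int((not flags["ctnnb1"]) + flags["tp53"] + (cn_fraction >= 39.0))
        hazard = config.baseline_hazard * config.hr_per_factor ** risk_count
        t_event = float(rng.exponential(1.0 / hazard))
        t_censor = float(rng.uniform(0.0, config.censor_window))
        surv_rows.append({"sample_id": sid,
                          "rfs_months": round(min(t_event, t_censor), 3),
                          "recurrence_event": int(t_event <= t_censor)})
        truth_rows.append({"sample_id": sid, **{f"{k}_mut": v for k, v in flags.items()},
                           "cn_high_component": high_cn, "cn_fraction": cn_fraction,
                           "risk_count": risk_count})

    cn_frame = pd.DataFrame(cn_cols, index=pd.Index(genes, name="gene_id"))
    maf_cols = ["Hugo_Symbol", "Chromosome", "Start_Position",
                "Variant_Classification", "Tumor_Sample_Barcode"]
    maf = pd.DataFrame(maf_rows, columns=maf_cols)
    return TCGAFixture(
        copynumber=GeneCopyNumberMatrix(cn_frame, value_kind="thresholded"),
        maf=maf,
        survival=pd.DataFrame(surv_rows, columns=["sample_id", "rfs_months",
                                                  "recurrence_event"]),
        ground_truth=pd.DataFrame(truth_rows),
    )
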