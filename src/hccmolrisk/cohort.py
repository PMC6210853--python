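"""Cohort data model and TSV readers/writers.

All on-disk tables are UTF-8 TSV with a header row, "." as the decimal
separator and empty cells for missing values.  Methylation files store
percent (0-100); in memory methylation is always a fraction in [0, 1] and
the conversion is applied exactly once, by the reader/writer pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROMOTER_MARKERS = ("APC", "CDKN2A", "RASSF1A", "HIC1", "GSTP1", "RUNX3", "SOCS1", "PRDM2")
REPEAT_MARKERS = ("Alu", "LINE1", "SAT2")
METHYLATION_MARKERS = PROMOTER_MARKERS + REPEAT_MARKERS

MUTATION_FLAGS = ("ctnnb1_mut", "tp53_mut", "tertp_mut")

CLINICAL_COLUMNS = (
    "sample_id", "sex", "age_years", "hbsag", "hcvab", "afp_ng_ml",
    "tumor_size_cm", "vascular_invasion", "tumor_number", "differentiation",
    "treatment", "rfs_months", "recurrence_event",
)

# categorical levels; "missing" is a first-class level for the three
# covariates whose totals vary across the association tables
_CATEGORICAL_LEVELS = {
    "sex": {"male", "female"},
    "hbsag": {"positive", "negative"},
    "hcvab": {"positive", "negative"},
    "vascular_invasion": {"presence", "absence", "missing"},
    "tumor_number": {"solitary", "multiple", "missing"},
    "differentiation": {"well", "moderately_poorly", "missing"},
    "treatment": {"resection", "transplantation"},
}
_MISSING_ALLOWED = {"vascular_invasion", "tumor_number", "differentiation"}

FEATURE_FLAGS = ("ctnnb1_mut", "tp53_mut", "tertp_mut", "tsg_hyper", "global_hypo", "fal_high")


class CohortValidationError(ValueError):
    """Raised when an input table violates the cohort schema."""


@dataclass
class GeneCopyNumberMatrix:
    """Gene x sample copy-number states.

    ``values`` is a genes-by-samples DataFrame; ``value_kind`` is
    ``"thresholded"`` (integer states -2..2) or ``"log_ratio"``
    (continuous log2 ratios).
    """

    values: pd.DataFrame
    value_kind: str = "thresholded"

    def __post_init__(self) -> None:
        if self.value_kind not in ("thresholded", "log_ratio"):
            raise CohortValidationError(f"unknown value_kind {self.value_kind!r}")
        if self.values.isna().any().any():
            raise CohortValidationError("copy-number matrix contains missing values")
        if self.value_kind == "thresholded":
            arr = self.values.to_numpy()
            if not np.isin(arr, (-2, -1, 0, 1, 2)).all():
                raise CohortValidationError("thresholded copy-number states must be in -2..2")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Cohort:
    """In-memory cohort: clinical covariates plus molecular measurements.

    All component frames are indexed by ``sample_id`` except
    ``microsatellites`` (long form, one row per typed locus).
    """

    clinical: pd.DataFrame
    mutations: pd.DataFrame
    methylation: pd.DataFrame  # fractions in [0, 1]
    microsatellites: pd.DataFrame  # columns: sample_id, locus_id, informative, imbalance
    copynumber: GeneCopyNumberMatrix | None = None
    provenance: str = ""

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical.index)

    @property
    def n_samples(self) -> int:
        return len(self.clinical)

    def promoter_matrix(self) -> pd.DataFrame:
        return self.methylation[list(PROMOTER_MARKERS)]

    def repeat_matrix(self) -> pd.DataFrame:
        return self.methylation[list(REPEAT_MARKERS)]

    def afp_high(self, cut: float = 200.0) -> pd.Series:
        """AFP dichotomized at ``cut`` ng/mL (>= cut is high)."""
        return self.clinical["afp_ng_ml"] >= cut

    def nbnc(self) -> pd.Series:
        """Non-B non-C etiology: negative for both HBsAg and HCV antibody."""
        return (self.clinical["hbsag"] == "negative") & (self.clinical["hcvab"] == "negative")

    def validate(self) -> None:
        ids = self.clinical.index
        if ids.has_duplicates:
            dupes = sorted(ids[ids.duplicated()].unique())
            raise CohortValidationError(f"duplicate sample_id: {dupes}")
        for name, frame in (("mutations", self.mutations), ("methylation", self.methylation)):
            missing = set(frame.index) - set(ids)
            if missing:
                raise CohortValidationError(
                    f"{name} table references unknown samples: {sorted(missing)}"
                )
        ms = self.microsatellites
        if len(ms):
            bad = ms.loc[ms["imbalance"] & ~ms["informative"]]
            if len(bad):
                raise CohortValidationError(
                    "imbalance called on non-informative loci: "
                    f"{bad[['sample_id', 'locus_id']].to_records(index=False).tolist()}"
                )
        meth = self.methylation
        if len(meth):
            out = (meth < 0) | (meth > 1)
            if out.any().any():
                sample = meth.index[out.any(axis=1)][0]
                marker = meth.columns[out.loc[sample]][0]
                raise CohortValidationError(
                    f"methylation value out of range for sample {sample!r}, marker {marker!r}"
                )


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required columns {missing}")


def _parse_clinical(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Parse and validate the clinical table; reject malformed rows with line numbers."""
    rows: list[dict] = []
    rejected: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        try:
            rec = {"sample_id": str(row["sample_id"])}
            for col in ("sex", "hbsag", "hcvab", "treatment"):
                val = row[col]
                if pd.isna(val) or val not in _CATEGORICAL_LEVELS[col]:
                    raise ValueError(f"bad {col} {val!r}")
                rec[col] = val
            for col in _MISSING_ALLOWED:
                val = row[col]
                if pd.isna(val) or val == "":
                    val = "missing"
                if val not in _CATEGORICAL_LEVELS[col]:
                    raise ValueError(f"bad {col} {val!r}")
                rec[col] = val
            for col, lo in (("age_years", 0.0), ("afp_ng_ml", 0.0),
                            ("tumor_size_cm", 0.0), ("rfs_months", 0.0)):
                val = float(row[col])
                if not np.isfinite(val) or val < lo or (
                    col in ("age_years", "tumor_size_cm") and val == 0.0
                ):
                    raise ValueError(f"bad {col} {row[col]!r}")
                rec[col] = val
            ev = int(row["recurrence_event"])
            if ev not in (0, 1):
                raise ValueError(f"bad recurrence_event {row['recurrence_event']!r}")
            rec["recurrence_event"] = ev
            rows.append(rec)
        except (ValueError, TypeError) as exc:
            rejected.append((lineno, str(exc)))
    if rejected:
        for lineno, msg in rejected:
            logger.warning("%s line %d rejected: %s", path, lineno, msg)
        raise CohortValidationError(
            f"{path}: {len(rejected)} malformed row(s), first at line "
            f"{rejected[0][0]}: {rejected[0][1]}"
        )
    out = pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS))
    return out.set_index("sample_id")


def read_cohort(directory: str | Path, copynumber_kind: str = "thresholded") -> Cohort:
    """Read a cohort from a directory of TSV tables.

    Expects ``samples.tsv``, ``mutations.tsv``, ``methylation.tsv`` and
    ``microsatellites.tsv``; ``copynumber.tsv`` is optional.  Raises
    :class:`CohortValidationError` on schema violations (duplicate sample
    ids, methylation outside 0-100, imbalance on non-informative loci,
    malformed rows — reported with line numbers).
    """
    directory = Path(directory)
    clin_path = directory / "samples.tsv"
    clin_raw = _read_tsv(clin_path)
    _require_columns(clin_raw, CLINICAL_COLUMNS, clin_path)
    clinical = _parse_clinical(clin_raw, clin_path)
    logger.info("%s: %d rows accepted", clin_path, len(clinical))

    mut_path = directory / "mutations.tsv"
    mut_raw = _read_tsv(mut_path)
    _require_columns(mut_raw, ("sample_id",) + MUTATION_FLAGS, mut_path)
    mutations = mut_raw.set_index("sample_id")[list(MUTATION_FLAGS)]
    try:
        mutations = mutations.astype(float).astype(int).astype(bool)
    except ValueError as exc:
        raise CohortValidationError(f"{mut_path}: non-binary mutation flag ({exc})") from exc

    meth_path = directory / "methylation.tsv"
    meth_raw = _read_tsv(meth_path)
    _require_columns(meth_raw, ("sample_id",) + METHYLATION_MARKERS, meth_path)
    meth = meth_raw.set_index("sample_id")[list(METHYLATION_MARKERS)].astype(float)
    out_of_range = (meth < 0) | (meth > 100)
    if out_of_range.any().any():
        sample = meth.index[out_of_range.any(axis=1)][0]
        marker = meth.columns[out_of_range.loc[sample]][0]
        raise CohortValidationError(
            f"{meth_path}: methylation value outside [0, 100] for sample "
            f"{sample!r}, marker {marker!r}"
        )
    methylation = meth / 100.0  # percent -> fraction, applied exactly once

    ms_path = directory / "microsatellites.tsv"
    ms_raw = _read_tsv(ms_path)
    _require_columns(ms_raw, ("sample_id", "locus_id", "informative", "imbalance"), ms_path)
    micro = ms_raw.copy()
    for col in ("informative", "imbalance"):
        micro[col] = micro[col].astype(float).astype(int).astype(bool)

    cn = None
    cn_path = directory / "copynumber.tsv"
    if cn_path.exists():
        cn_frame = pd.read_csv(cn_path, sep="\t", index_col="gene_id")
        cn = GeneCopyNumberMatrix(cn_frame, value_kind=copynumber_kind)

    cohort = Cohort(
        clinical=clinical,
        mutations=mutations,
        methylation=methylation,
        microsatellites=micro,
        copynumber=cn,
        provenance=f"read from {directory}",
    )
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write all cohort tables as TSV (methylation back on the percent scale)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    clin = cohort.clinical.reset_index()
    clin.to_csv(directory / "samples.tsv", sep="\t", index=False, float_format="%.6g")

    mut = cohort.mutations.astype(int).reset_index()
    mut.to_csv(directory / "mutations.tsv", sep="\t", index=False)

    meth = (cohort.methylation * 100.0).reset_index()
    meth.to_csv(directory / "methylation.tsv", sep="\t", index=False, float_format="%.4f")

    ms = cohort.microsatellites.copy()
    for col in ("informative", "imbalance"):
        ms[col] = ms[col].astype(int)
    ms.to_csv(directory / "microsatellites.tsv", sep="\t", index=False)

    if cohort.copynumber is not None:
        cn = cohort.copynumber.values.copy()
        cn.index.name = "gene_id"
        fmt = None if cohort.copynumber.value_kind == "thresholded" else "%.4f"
        cn.to_csv(directory / "copynumber.tsv", sep="\t", float_format=fmt)


# MAF variant classifications that alter the protein; anything else is a non-call.
NONSYNONYMOUS_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Splice_Site", "Translation_Start_Site",
})

# GRCh37 coordinates used when the MAF carries positions: CTNNB1 exon 3,
# TP53 exons 5-8 (spanned), and the TERT promoter hotspots at -124/-146 bp
# from the ATG (chr5:1,295,228 and 1,295,250).
DEFAULT_GENE_RULES: dict = {
    "ctnnb1_region": ("3", 41_266_017, 41_266_244),
    "tp53_region": ("17", 7_577_019, 7_578_554),
    "tert_positions": ("5", (1_295_228, 1_295_250)),
    "tert_position_window": 2,
    "use_positions": "auto",  # "auto" | "always" | "never"
}


def _in_region(chrom: str, pos: float, region: tuple[str, int, int]) -> bool:
    want_chrom, start, end = region
    return str(chrom).removeprefix("chr") == want_chrom and start <= pos <= end


def read_maf_mutations(
    path: str | Path,
    sample_ids: list[str] | None = None,
    gene_rules: dict | None = None,
) -> pd.DataFrame:
    """Derive the three mutation flags from a MAF-subset file.

    A sample is CTNNB1-mutant iff it has a nonsynonymous CTNNB1 call
    (restricted to exon 3 when genomic coordinates are present), TP53-mutant
    analogously for exons 5-8, and TERT-promoter-mutant iff it has a TERT
    variant at the -124/-146 hotspots (any TERT 5'Flank/promoter call when
    coordinates are absent).  Returns a boolean DataFrame indexed by sample
    with columns ``ctnnb1_mut, tp53_mut, tertp_mut``; ``sample_ids`` adds
    rows (all-False) for samples with no calls.
    """
    rules = dict(DEFAULT_GENE_RULES)
    if gene_rules:
        rules.update(gene_rules)
    path = Path(path)
    maf = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")
    _require_columns(maf, required, path)
    have_pos = {"Chromosome", "Start_Position"} <= set(maf.columns)
    mode = rules["use_positions"]
    use_pos = have_pos if mode == "auto" else (mode == "always")
    if mode == "always" and not have_pos:
        raise CohortValidationError(f"{path}: positional filtering requested but no coordinates")

    known = NONSYNONYMOUS_CLASSES | {"5'Flank", "5'UTR", "Silent", "Intron", "3'UTR", "RNA", "IGR"}
    unknown = set(maf["Variant_Classification"]) - known
    if unknown:
        logger.warning("%s: %d unknown variant classifications treated as non-calls: %s",
                       path, len(unknown), sorted(unknown))

    samples = sorted(set(maf["Tumor_Sample_Barcode"]) | set(sample_ids or []))
    flags = pd.DataFrame(False, index=pd.Index(samples, name="sample_id"),
                         columns=list(MUTATION_FLAGS))
    for _, row in maf.iterrows():
        gene = row["Hugo_Symbol"]
        vclass = row["Variant_Classification"]
        sample = row["Tumor_Sample_Barcode"]
        chrom = row.get("Chromosome", "")
        pos = float(row["Start_Position"]) if use_pos and row.get("Start_Position") else np.nan
        if gene == "CTNNB1" and vclass in NONSYNONYMOUS_CLASSES:
            if not use_pos or _in_region(chrom, pos, rules["ctnnb1_region"]):
                flags.loc[sample, "ctnnb1_mut"] = True
        elif gene == "TP53" and vclass in NONSYNONYMOUS_CLASSES:
            if not use_pos or _in_region(chrom, pos, rules["tp53_region"]):
                flags.loc[sample, "tp53_mut"] = True
        elif gene == "TERT":
            # promoter variants are upstream of the CDS, never protein-altering
            if vclass in ("5'Flank", "5'UTR"):
                if not use_pos:
                    flags.loc[sample, "tertp_mut"] = True
                else:
                    tchrom, hotspots = rules["tert_positions"]
                    window = rules["tert_position_window"]
                    if str(chrom).removeprefix("chr") == tchrom and any(
                        abs(pos - h) <= window for h in hotspots
                    ):
                        flags.loc[sample, "tertp_mut"] = True
    if sample_ids is not None:
        flags = flags.reindex(sample_ids, fill_value=False)
        flags.index.name = "sample_id"
    return flags


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write the per-sample molecular feature table.

    ``features`` is indexed by sample_id with the six boolean flags plus
    ``fal_percent``.  Flags are serialized as 0/1, FAL as percent with one
    decimal; column order is fixed.
    """
    out = pd.DataFrame(index=features.index)
    for flag in FEATURE_FLAGS:
        out[flag] = features[flag].astype(int)
    out["fal_percent"] = features["fal_percent"].map(
        lambda v: "" if pd.isna(v) else f"{v:.1f}"
    )
    out.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, sep="\t", index=False
    )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t").set_index("sample_id")
    for flag in FEATURE_FLAGS:
        df[flag] = df[flag].astype(bool)
    df["fal_percent"] = df["fal_percent"].astype(float)
    return df
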