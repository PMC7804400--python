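"""Allelic-imbalance quantification and testing from qPCR dCt measurements.

For each heterozygous donor the two alleles of a transcript are read on
separate dye channels, and the per-replicate allelic ratio is carried as

    dCt = Ct(FAM) - Ct(VIC),

which is -log2 of the FAM:VIC template ratio under equal amplification
efficiency.  Because the two probes never amplify perfectly equally, the
dCt of heterozygous genomic DNA -- where the alleles are present exactly
1:1 -- defines the balanced baseline, and the normalized value

    ndCt = dCt(cDNA replicate) - mean dCt(all gDNA replicates)

cancels dye and amplification bias: ndCt = 0 means balanced allelic
expression, ndCt < 0 means the FAM allele is the more expressed.  Group
differences are tested with the Mann-Whitney U rank-sum test (the dCt
distributions are frequently non-normal, which a Shapiro-Wilk screen
documents), per sample against the pooled gDNA replicates and overall with
all cDNA replicates pooled against all gDNA replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class RankSumResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str


@dataclass
class AseSampleResult:
    """Allelic imbalance of one heterozygous cDNA sample on one assay."""

    sample_id: str
    assay_id: str
    tissue: str
    diagnosis: str
    delta_cts: list[float]
    mean_delta_ct: float
    n_delta_ct: float
    fold_change: float
    p_value: float
    significant: bool
    n_replicates_used: int


@dataclass
class AseAssayResult:
    """Pooled allelic-expression verdict for one assay in one tissue."""

    assay_id: str
    gene: str
    tissue: str
    n_het: int
    risk_allele: str
    direction_label: str
    risk_allele_direction: str
    overall_p: float
    ase_detected: bool
    mean_n_delta_ct: float
    fold_change: float
    consistency: float
    diagnosis_p: float | None
    maf: float | None = None
    sample_results: list[AseSampleResult] = field(default_factory=list)


def compute_delta_ct(well) -> float | None:
    """Per-replicate dCt = ct_fam - ct_vic; ``None`` if either channel censored."""
    ct_fam, ct_vic = well["ct_fam"], well["ct_vic"]
    if pd.isna(ct_fam) or pd.isna(ct_vic):
        return None
    return float(ct_fam) - float(ct_vic)


def apply_ct_exclusion(
    wells: pd.DataFrame,
    ct_cutoff: float = 36.0,
    min_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-expression replicates and under-replicated samples.

    A replicate is dropped when either channel is censored or above
    ``ct_cutoff`` (Ct beyond the cut-off indicates too little template to
    quantify reliably); a (sample, assay) group is dropped entirely when
    fewer than ``min_replicates`` replicates survive.  Returns the
    surviving wells and a log with one row per dropped replicate or group.
    """
    log_rows = []
    fam = wells["ct_fam"]
    vic = wells["ct_vic"]
    bad = fam.isna() | vic.isna() | (fam > ct_cutoff) | (vic > ct_cutoff)
    for row in wells[bad].itertuples():
        reason = "CENSORED" if (pd.isna(row.ct_fam) or pd.isna(row.ct_vic)) \
            else "CT_ABOVE_CUTOFF"
        log_rows.append(
            {"sample_id": row.sample_id, "assay_id": row.assay_id,
             "replicate": row.replicate, "reason": reason}
        )
    surviving = wells[~bad]

    counts = surviving.groupby(["sample_id", "assay_id"]).size()
    under = counts[counts < min_replicates]
    for (sample, assay), n in under.items():
        log_rows.append(
            {"sample_id": sample, "assay_id": assay, "replicate": None,
             "reason": f"TOO_FEW_REPLICATES({n})"}
        )
    if len(under):
        keep_keys = set(counts[counts >= min_replicates].index)
        mask = [
            (s, a) in keep_keys
            for s, a in zip(surviving["sample_id"], surviving["assay_id"])
        ]
        surviving = surviving[np.array(mask, dtype=bool)]
    log = pd.DataFrame(log_rows,
                       columns=["sample_id", "assay_id", "replicate", "reason"])
    return surviving.reset_index(drop=True), log


def normalize(
    sample_dcts: Sequence[float], gdna_dcts: Sequence[float]
) -> tuple[np.ndarray, float]:
    """gDNA-normalize replicate dCt values.

    Returns the per-replicate ndCt values (each dCt minus the mean of all
    gDNA dCt values for the assay) and their sample-level mean.
    """
    gdna = np.asarray(gdna_dcts, dtype=float)
    if gdna.size == 0:
        raise ValueError("normalization requires at least one gDNA heterozygote dCt")
    ndct = np.asarray(sample_dcts, dtype=float) - gdna.mean()
    return ndct, float(ndct.mean())


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Uses exact enumeration of the U distribution when the pooled size is
    at most 12 and there are no ties, and the tie-corrected normal
    approximation otherwise.  Two identical constant groups carry no
    ordering information: p = 1 by convention, flagged as ``degenerate``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = x.size * y.size / 2.0
        return RankSumResult(u, 1.0, "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 12 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankSumResult(float(res.statistic), float(res.pvalue), "exact")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankSumResult(float(res.statistic), float(res.pvalue), "asymptotic")


def normality_screen(
    cdna_dcts: Sequence[float],
    gdna_dcts: Sequence[float],
    alpha: float = 0.05,
) -> dict:
    """Shapiro-Wilk screen of both dCt groups.

    Documents whether normality is rejected anywhere (motivating the
    nonparametric rank-sum test); it never changes which test is run.
    Groups smaller than 3 are skipped with a note.
    """
    report: dict = {"alpha": alpha, "groups": {}, "any_rejected": False}
    for name, values in (("cDNA", cdna_dcts), ("gDNA", gdna_dcts)):
        arr = np.asarray(values, dtype=float)
        if arr.size < 3:
            report["groups"][name] = {"n": int(arr.size), "skipped": True,
                                      "note": "group too small for Shapiro-Wilk"}
            continue
        if np.all(arr == arr[0]):
            report["groups"][name] = {"n": int(arr.size), "skipped": True,
                                      "note": "constant group"}
            continue
        w, p = stats.shapiro(arr)
        rejected = bool(p < alpha)
        report["groups"][name] = {"n": int(arr.size), "skipped": False,
                                  "W": float(w), "p": float(p),
                                  "rejected": rejected}
        report["any_rejected"] = report["any_rejected"] or rejected
    return report


def adjust_sample_significance(
    results: Sequence[AseSampleResult], alpha: float = 0.05
) -> list[AseSampleResult]:
    """Benjamini-Hochberg adjustment across per-sample p-values.

    Optional and off by default in the pipeline (per-sample calls are
    descriptive; the assay verdict comes from the pooled test).  Returns
    new results with adjusted ``p_value`` and re-derived ``significant``.
    """
    results = list(results)
    if not results:
        return []
    adjusted = stats.false_discovery_control(
        [r.p_value for r in results], method="bh"
    )
    out = []
    for r, p_adj in zip(results, adjusted):
        updated = AseSampleResult(**{**r.__dict__, "p_value": float(p_adj),
                                     "significant": bool(p_adj <= alpha)})
        out.append(updated)
    return out


def _direction_label(mean_ndct: float, significant: bool,
                     fam_allele: str, vic_allele: str) -> tuple[str, str]:
    """Map the sign of mean ndCt through the dye->allele orientation.

    Negative ndCt means the FAM channel crossed threshold earlier than its
    gDNA baseline, i.e. the FAM-read allele is the more expressed.
    """
    if not significant:
        return f"{fam_allele}={vic_allele}", "none"
    if mean_ndct < 0:
        return f"{fam_allele}>{vic_allele}", fam_allele
    return f"{fam_allele}<{vic_allele}", vic_allele


def assay_summary(
    sample_results: Sequence[AseSampleResult],
    cdna_dcts: Sequence[float],
    gdna_dcts: Sequence[float],
    assay_info: Mapping[str, str],
    alpha: float = 0.05,
    maf: float | None = None,
) -> AseAssayResult:
    """Pooled per-assay verdict: all cDNA replicates vs all gDNA replicates.

    ``assay_info`` must provide gene, risk_allele, fam_allele and
    vic_allele for the assay.  The ASE call is driven by the pooled test;
    the fraction of individually significant samples sharing the pooled
    sign is reported as a consistency metric but does not gate the call.
    """
    results = list(sample_results)
    if not results:
        raise ValueError(
            f"assay {assay_info.get('assay_id', '?')}: no heterozygous cDNA samples"
        )
    assay_id = results[0].assay_id
    tissue = results[0].tissue
    overall = rank_sum_test(cdna_dcts, gdna_dcts)
    detected = overall.pvalue <= alpha

    ndcts = np.array([r.n_delta_ct for r in results])
    mean_ndct = float(ndcts.mean())
    label, more_expressed = _direction_label(
        mean_ndct, detected, assay_info["fam_allele"], assay_info["vic_allele"]
    )
    if more_expressed == "none":
        risk_dir = "none"
    else:
        risk_dir = "more" if more_expressed == assay_info["risk_allele"] else "less"

    agreeing = [
        r for r in results
        if r.significant and np.sign(r.n_delta_ct) == np.sign(mean_ndct)
    ]
    consistency = len(agreeing) / len(results)

    pd_nd = [r.n_delta_ct for r in results if r.diagnosis == "PD"]
    ctrl_nd = [r.n_delta_ct for r in results if r.diagnosis == "control"]
    diagnosis_p = (
        rank_sum_test(pd_nd, ctrl_nd).pvalue if pd_nd and ctrl_nd else None
    )

    return AseAssayResult(
        assay_id=assay_id,
        gene=assay_info["gene"],
        tissue=tissue,
        n_het=len(results),
        risk_allele=assay_info["risk_allele"],
        direction_label=label,
        risk_allele_direction=risk_dir,
        overall_p=float(overall.pvalue),
        ase_detected=bool(detected),
        mean_n_delta_ct=mean_ndct,
        fold_change=float(2.0 ** abs(mean_ndct)),
        consistency=consistency,
        diagnosis_p=diagnosis_p,
        maf=maf,
        sample_results=results,
    )


def analyze_assay(
    wells: pd.DataFrame,
    meta: pd.DataFrame,
    het_samples: Sequence[str] | None,
    assay_info: Mapping[str, str],
    alpha: float = 0.05,
    ct_cutoff: float = 36.0,
    min_replicates: int = 3,
    comparator: str = "pooled",
    maf: float | None = None,
) -> AseAssayResult:
    """Run the full allelic-expression analysis for one assay in one tissue.

    ``wells`` holds both gDNA and cDNA replicate measurements for the
    assay; ``het_samples`` restricts the analysis to heterozygous donors
    (``None`` uses every sample present).  ``comparator`` selects the gDNA
    reference for the per-sample tests: ``"pooled"`` compares each cDNA
    sample's replicates against all pooled gDNA replicate dCts,
    ``"sample_means"`` against the per-sample gDNA mean dCts.
    """
    if comparator not in ("pooled", "sample_means"):
        raise ValueError(f"unknown comparator {comparator!r}")
    assay_id = str(assay_info["assay_id"])
    sub = wells[wells["assay_id"] == assay_id]
    if het_samples is not None:
        sub = sub[sub["sample_id"].isin(set(het_samples))]
    surviving, _ = apply_ct_exclusion(sub, ct_cutoff, min_replicates)

    meta_ix = meta.drop_duplicates("sample_id").set_index("sample_id")
    dct = surviving["ct_fam"] - surviving["ct_vic"]
    frame = surviving.assign(delta_ct=dct)
    frame = frame.assign(
        material=[meta_ix.at[s, "material"] for s in frame["sample_id"]],
        tissue=[meta_ix.at[s, "tissue"] for s in frame["sample_id"]],
        diagnosis=[meta_ix.at[s, "diagnosis"] for s in frame["sample_id"]],
    )

    gdna = frame[frame["material"] == "gDNA"]
    cdna = frame[frame["material"] == "cDNA"]
    gdna_dcts = gdna["delta_ct"].to_numpy()
    if gdna_dcts.size == 0:
        raise ValueError(f"assay {assay_id}: no surviving gDNA heterozygote replicates")
    gdna_mean = float(gdna_dcts.mean())
    gdna_sample_means = gdna.groupby("sample_id")["delta_ct"].mean().to_numpy()

    sample_results = []
    for sample, grp in cdna.groupby("sample_id", sort=True):
        dcts = grp["delta_ct"].to_numpy()
        ndct_reps, ndct = normalize(dcts, gdna_dcts)
        reference = gdna_dcts if comparator == "pooled" else gdna_sample_means
        test = rank_sum_test(dcts, reference)
        sample_results.append(
            AseSampleResult(
                sample_id=str(sample),
                assay_id=assay_id,
                tissue=str(grp["tissue"].iloc[0]),
                diagnosis=str(grp["diagnosis"].iloc[0]),
                delta_cts=[float(v) for v in dcts],
                mean_delta_ct=float(dcts.mean()),
                n_delta_ct=ndct,
                fold_change=float(2.0 ** abs(ndct)),
                p_value=float(test.pvalue),
                significant=bool(test.pvalue <= alpha),
                n_replicates_used=int(dcts.size),
            )
        )

    return assay_summary(
        sample_results,
        cdna["delta_ct"].to_numpy(),
        gdna_dcts,
        {**assay_info, "assay_id": assay_id},
        alpha=alpha,
        maf=maf,
    )


CONCORDANT = "concordant_ase"
BRAIN_SPECIFIC = "brain_specific"
BLOOD_SPECIFIC = "blood_specific"
DISCORDANT = "discordant_direction"
NO_ASE = "no_ase"
INCOMPARABLE = "incomparable"


def compare_tissues(
    brain: Sequence[AseAssayResult], blood: Sequence[AseAssayResult]
) -> pd.DataFrame:
    """Classify each assay's cross-tissue behaviour.

    ``concordant_ase`` -- ASE detected in both tissues with the same sign;
    ``discordant_direction`` -- detected in both with opposite signs;
    ``brain_specific`` / ``blood_specific`` -- detected in one tissue only;
    ``no_ase`` -- detected in neither; assays measured in a single tissue
    are reported ``incomparable``.
    """
    brain_by_id = {r.assay_id: r for r in brain}
    blood_by_id = {r.assay_id: r for r in blood}
    rows = []
    for assay_id in sorted(set(brain_by_id) | set(blood_by_id)):
        b = brain_by_id.get(assay_id)
        w = blood_by_id.get(assay_id)
        if b is None or w is None:
            present = b or w
            rows.append(
                {"assay_id": assay_id, "gene": present.gene, "class": INCOMPARABLE,
                 "brain_p": b.overall_p if b else None,
                 "blood_p": w.overall_p if w else None}
            )
            continue
        if b.ase_detected and w.ase_detected:
            same_sign = np.sign(b.mean_n_delta_ct) == np.sign(w.mean_n_delta_ct)
            cls = CONCORDANT if same_sign else DISCORDANT
        elif b.ase_detected:
            cls = BRAIN_SPECIFIC
        elif w.ase_detected:
            cls = BLOOD_SPECIFIC
        else:
            cls = NO_ASE
        rows.append(
            {"assay_id": assay_id, "gene": b.gene, "class": cls,
             "brain_p": b.overall_p, "blood_p": w.overall_p}
        )
    return pd.DataFrame(rows, columns=["assay_id", "gene", "class",
                                       "brain_p", "blood_p"])
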