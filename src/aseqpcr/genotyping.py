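"""Heterozygote identification from gDNA allele-discrimination qPCR.

Only heterozygous donors are informative for allelic expression, so every
donor's gDNA is genotyped first.  Calls are made from replicate Ct pairs:
a channel that never amplifies marks a homozygote for the other allele,
while two amplifying channels with a near-balanced Ct difference (after
correcting the assay's dye bias) mark a heterozygote.  Ambiguous evidence
yields NO_CALL, never a forced call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

HOM_FAM = "HOM_FAM"
HOM_VIC = "HOM_VIC"
HET = "HET"
NO_CALL = "NO_CALL"


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    assay_id: str
    call: str
    delta_ct: float | None = None
    quality_note: str = ""


def _channel_state(cts: np.ndarray, dropout_ct: float) -> str:
    """'amplified' if every replicate crossed threshold early enough,
    'dropped' if none did, 'mixed' otherwise."""
    ok = np.array([(not math.isnan(ct)) and ct <= dropout_ct for ct in cts])
    if ok.all():
        return "amplified"
    if not ok.any():
        return "dropped"
    return "mixed"


def call_genotype(
    wells: pd.DataFrame,
    het_window: float = 1.5,
    dropout_ct: float = 36.0,
    dye_bias: float = 0.0,
) -> GenotypeCall:
    """Call one gDNA sample's genotype from its replicate wells.

    ``dye_bias`` is the assay's expected gDNA dCt for a heterozygote
    (estimated cohort-wide by :func:`call_cohort`); a sample is HET when
    both channels amplify in all replicates and its mean dCt lies within
    ``het_window`` of that estimate.
    """
    if len(wells) == 0:
        raise ValueError("at least one replicate well is required")
    samples = wells["sample_id"].unique()
    assays = wells["assay_id"].unique()
    if len(samples) != 1 or len(assays) != 1:
        raise ValueError("call_genotype expects wells of a single (sample, assay) group")
    sample_id, assay_id = str(samples[0]), str(assays[0])

    fam = wells["ct_fam"].to_numpy(dtype=float)
    vic = wells["ct_vic"].to_numpy(dtype=float)
    fam_state = _channel_state(fam, dropout_ct)
    vic_state = _channel_state(vic, dropout_ct)

    if fam_state == "amplified" and vic_state == "dropped":
        return GenotypeCall(sample_id, assay_id, HOM_FAM,
                            quality_note="VIC channel fully dropped out")
    if vic_state == "amplified" and fam_state == "dropped":
        return GenotypeCall(sample_id, assay_id, HOM_VIC,
                            quality_note="FAM channel fully dropped out")
    if fam_state == "amplified" and vic_state == "amplified":
        delta = float(np.mean(fam - vic))
        if abs(delta - dye_bias) <= het_window:
            return GenotypeCall(sample_id, assay_id, HET, delta_ct=delta)
        return GenotypeCall(
            sample_id, assay_id, NO_CALL, delta_ct=delta,
            quality_note=f"mean dCt {delta:.2f} outside het window "
                         f"{dye_bias:+.2f} +/- {het_window}",
        )
    return GenotypeCall(sample_id, assay_id, NO_CALL,
                        quality_note="inconsistent channel dropout across replicates")


def estimate_dye_bias(gdna_wells: pd.DataFrame, dropout_ct: float = 36.0) -> float:
    """Median gDNA dCt over confidently bi-allelic samples for one assay.

    In gDNA every heterozygote carries the alleles 1:1, so the median dCt
    of samples where both channels amplify estimates the assay's dye bias
    robustly (homozygotes do not contribute: one of their channels drops).
    """
    deltas = []
    for _, grp in gdna_wells.groupby("sample_id"):
        fam = grp["ct_fam"].to_numpy(dtype=float)
        vic = grp["ct_vic"].to_numpy(dtype=float)
        if _channel_state(fam, dropout_ct) == "amplified" and \
           _channel_state(vic, dropout_ct) == "amplified":
            deltas.append(float(np.mean(fam - vic)))
    return float(np.median(deltas)) if deltas else 0.0


def call_cohort(
    wells: pd.DataFrame,
    meta: pd.DataFrame,
    het_window: float = 1.5,
    dropout_ct: float = 36.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype every gDNA sample and build the per-assay heterozygote roster.

    Returns ``(calls, roster)``: one call per (sample, assay), and the HET
    donors per assay and tissue that feed the allelic expression stage.
    """
    meta_ix = meta.set_index("sample_id")
    well_samples = set(wells["sample_id"])
    unknown = sorted(well_samples - set(meta_ix.index))
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown[:5]}")
    non_gdna = sorted(s for s in well_samples if meta_ix.at[s, "material"] != "gDNA")
    if non_gdna:
        raise ValueError(
            f"genotype calling is gDNA-only; got non-gDNA samples {non_gdna[:5]}"
        )
    gwells = wells

    dup = gwells.duplicated(["sample_id", "assay_id", "replicate"])
    if dup.any():
        raise ValueError("duplicate (sample, assay, replicate) wells in genotyping plate")

    rows = []
    for assay, assay_wells in gwells.groupby("assay_id", sort=True):
        bias = estimate_dye_bias(assay_wells, dropout_ct)
        for sample, grp in assay_wells.groupby("sample_id", sort=True):
            call = call_genotype(grp, het_window, dropout_ct, dye_bias=bias)
            rows.append(
                {"sample_id": sample, "assay_id": assay, "call": call.call,
                 "delta_ct": call.delta_ct, "quality_note": call.quality_note,
                 "donor_id": meta_ix.at[sample, "donor_id"],
                 "tissue": meta_ix.at[sample, "tissue"]}
            )
    calls = pd.DataFrame(
        rows, columns=["sample_id", "assay_id", "call", "delta_ct",
                       "quality_note", "donor_id", "tissue"]
    )
    roster = (
        calls.loc[calls["call"] == HET,
                  ["assay_id", "tissue", "donor_id", "sample_id"]]
        .sort_values(["assay_id", "tissue", "donor_id"])
        .reset_index(drop=True)
    )
    return calls, roster
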