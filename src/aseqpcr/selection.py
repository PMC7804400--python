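"""Selection of transcribed marker SNPs for allelic expression analysis.

A GWAS locus is usually tagged by a non-coding lead SNP; to measure allelic
expression by qPCR one needs a *transcribed* marker -- the lead SNP itself
when it is coding, otherwise a proxy SNP in strong linkage disequilibrium
that falls in an exonic or UTR region of a nearby gene.  This module applies
the selection workflow to a candidate table of lead/proxy pairs:

1. keep proxies in strong LD with the lead (r^2 at or above a cut-off);
2. keep only transcribed annotations (coding or UTR);
3. drop markers inside complex polymorphic inversion regions and markers
   present only in a restricted transcript isoform;
4. drop markers whose genotyping assay failed calibration (a replacement
   proxy, when present in the table, is picked up by the per-locus rule);
5. drop assays whose gene is essentially unexpressed in the target tissue
   (more than half of cDNA samples beyond the Ct cut-off);
6. keep one marker per locus and gene, preferring a transcribed lead SNP,
   then the highest r^2; independent secondary association signals are
   exempt from the cap.

Every input candidate ends up either selected or excluded with a reason
code, so the report is a complete audit trail of the workflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

TRANSCRIBED_ANNOTATIONS = frozenset({"synonymous", "missense", "3'UTR", "5'UTR"})
NON_TRANSCRIBED_ANNOTATIONS = frozenset({"intronic", "intergenic"})
VALID_ANNOTATIONS = TRANSCRIBED_ANNOTATIONS | NON_TRANSCRIBED_ANNOTATIONS

#: Closed enumeration of exclusion reason codes.
REASON_LOW_LD = "LOW_LD"
REASON_NOT_TRANSCRIBED = "NOT_TRANSCRIBED"
REASON_INVERSION_LOCUS = "INVERSION_LOCUS"
REASON_ISOFORM_RESTRICTED = "ISOFORM_RESTRICTED"
REASON_ASSAY_FAILED = "ASSAY_FAILED"
REASON_LOW_EXPRESSION = "LOW_EXPRESSION"
REASON_LOCUS_REDUNDANT = "LOCUS_REDUNDANT"

_ANNOTATION_PRIORITY = {"missense": 0, "synonymous": 0, "3'UTR": 1, "5'UTR": 1}


@dataclass(frozen=True)
class CandidateVariant:
    """One lead/proxy SNP pair with LD and annotation metadata."""

    lead_snp: str
    proxy_snp: str
    gene: str
    r2: float
    dprime: float
    annotation: str
    locus_id: str
    is_secondary_signal: bool = False
    in_inversion_region: bool = False
    isoform_restricted: bool = False
    assay_failed: bool = False
    technology: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must be in [0, 1], got {self.r2} for {self.proxy_snp}")
        if abs(self.dprime) > 1.0 + 1e-12:
            raise ValueError(f"|D'| must be <= 1, got {self.dprime} for {self.proxy_snp}")

    @property
    def is_transcribed_lead(self) -> bool:
        return self.proxy_snp == self.lead_snp and self.annotation in TRANSCRIBED_ANNOTATIONS


@dataclass
class SelectionReport:
    """Outcome of one or more selection stages.

    ``selected`` and ``excluded`` always partition the input; ``stage_counts``
    records, per stage, how many candidates entered and how many each reason
    removed.
    """

    selected: list[CandidateVariant]
    excluded: list[tuple[CandidateVariant, str]]
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.selected) + len(self.excluded)

    @property
    def selected_genes(self) -> set[str]:
        return {c.gene for c in self.selected}

    def exclusion_reason(self, proxy_snp: str) -> str | None:
        for cand, reason in self.excluded:
            if cand.proxy_snp == proxy_snp:
                return reason
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [{**_as_dict(c), "status": "selected", "reason": ""} for c in self.selected]
        rows += [{**_as_dict(c), "status": "excluded", "reason": r} for c, r in self.excluded]
        return pd.DataFrame(rows)

    def summary_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_selected": len(self.selected),
                "n_excluded": len(self.excluded),
                "n_genes": len(self.selected_genes),
                "stage_counts": self.stage_counts,
            },
            indent=2,
        )


def _as_dict(c: CandidateVariant) -> dict:
    return {
        "lead_snp": c.lead_snp, "proxy_snp": c.proxy_snp, "gene": c.gene,
        "r2": c.r2, "dprime": c.dprime, "annotation": c.annotation,
        "locus_id": c.locus_id, "is_secondary_signal": c.is_secondary_signal,
        "in_inversion_region": c.in_inversion_region,
        "isoform_restricted": c.isoform_restricted,
        "assay_failed": c.assay_failed, "technology": c.technology or "",
    }


def _stage_report(
    name: str,
    kept: list[CandidateVariant],
    dropped: list[tuple[CandidateVariant, str]],
) -> SelectionReport:
    counts: dict[str, int] = {"input": len(kept) + len(dropped), "selected": len(kept)}
    for _, reason in dropped:
        counts[reason] = counts.get(reason, 0) + 1
    return SelectionReport(kept, dropped, {name: counts})


def filter_ld(
    candidates: Sequence[CandidateVariant], threshold: float = 0.6
) -> SelectionReport:
    """Keep candidates whose proxy is in LD r^2 >= ``threshold`` with the lead."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"LD threshold must be in [0, 1], got {threshold}")
    kept, dropped = [], []
    for c in candidates:
        if c.r2 >= threshold:
            kept.append(c)
        else:
            dropped.append((c, REASON_LOW_LD))
    return _stage_report("ld", kept, dropped)


def filter_transcribed(candidates: Sequence[CandidateVariant]) -> SelectionReport:
    """Keep coding and UTR variants; drop intronic/intergenic candidates."""
    kept, dropped = [], []
    for c in candidates:
        if c.annotation not in VALID_ANNOTATIONS:
            raise ValueError(
                f"unknown annotation {c.annotation!r} for {c.proxy_snp}; "
                f"expected one of {sorted(VALID_ANNOTATIONS)}"
            )
        if c.annotation in TRANSCRIBED_ANNOTATIONS:
            kept.append(c)
        else:
            dropped.append((c, REASON_NOT_TRANSCRIBED))
    return _stage_report("transcribed", kept, dropped)


def filter_special_regions(candidates: Sequence[CandidateVariant]) -> SelectionReport:
    """Drop inversion-region markers and isoform-restricted markers."""
    kept, dropped = [], []
    for c in candidates:
        if c.in_inversion_region:
            dropped.append((c, REASON_INVERSION_LOCUS))
        elif c.isoform_restricted:
            dropped.append((c, REASON_ISOFORM_RESTRICTED))
        else:
            kept.append(c)
    return _stage_report("special_regions", kept, dropped)


def filter_assay_status(candidates: Sequence[CandidateVariant]) -> SelectionReport:
    """Drop markers whose genotyping assay failed calibration."""
    kept, dropped = [], []
    for c in candidates:
        if c.assay_failed:
            dropped.append((c, REASON_ASSAY_FAILED))
        else:
            kept.append(c)
    return _stage_report("assay_status", kept, dropped)


def filter_low_expression(
    candidate: CandidateVariant,
    cdna_cts: Sequence[float],
    ct_cutoff: float = 36.0,
    fraction: float = 0.5,
) -> bool:
    """``True`` if the marker's gene is sufficiently expressed to assay.

    A cDNA sample counts against the marker when its Ct exceeds
    ``ct_cutoff`` (a censored/undetermined measurement always does); the
    marker is rejected when strictly more than ``fraction`` of samples do.
    """
    cts = list(cdna_cts)
    if not cts:
        raise ValueError(f"no cDNA Ct values supplied for {candidate.proxy_snp}")
    n_high = sum(1 for ct in cts if (ct is None) or math.isnan(ct) or ct > ct_cutoff)
    return not (n_high / len(cts) > fraction)


def select_one_per_locus(candidates: Sequence[CandidateVariant]) -> SelectionReport:
    """Keep one marker per (locus, gene) pair.

    A transcribed lead SNP always wins its group; otherwise the highest-r^2
    proxy wins, ties broken by coding-over-UTR annotation and then by rsID.
    Independent secondary association signals bypass the cap.
    """
    kept, dropped = [], []
    groups: dict[tuple[str, str], list[CandidateVariant]] = {}
    for c in candidates:
        if c.is_secondary_signal:
            kept.append(c)
        else:
            groups.setdefault((c.locus_id, c.gene), []).append(c)
    for group in groups.values():
        ranked = sorted(
            group,
            key=lambda c: (
                not c.is_transcribed_lead,
                -c.r2,
                _ANNOTATION_PRIORITY.get(c.annotation, 9),
                c.proxy_snp,
            ),
        )
        kept.append(ranked[0])
        dropped.extend((c, REASON_LOCUS_REDUNDANT) for c in ranked[1:])
    return _stage_report("one_per_locus", kept, dropped)


def run_selection(
    candidates: Sequence[CandidateVariant],
    ld_threshold: float = 0.6,
    ct_cutoff: float = 36.0,
    expression_fraction: float = 0.5,
    cdna_cts: Mapping[str, Sequence[float]] | None = None,
) -> SelectionReport:
    """Compose the full marker-selection workflow.

    ``cdna_cts`` maps proxy rsIDs to observed cDNA Ct values for the
    low-expression stage; markers without Ct data skip that stage.
    """
    excluded: list[tuple[CandidateVariant, str]] = []
    stage_counts: dict[str, dict[str, int]] = {}
    current = list(candidates)

    stages = [
        lambda cs: filter_ld(cs, ld_threshold),
        filter_transcribed,
        filter_special_regions,
        filter_assay_status,
    ]
    for stage in stages:
        rep = stage(current)
        excluded.extend(rep.excluded)
        stage_counts.update(rep.stage_counts)
        current = rep.selected

    if cdna_cts is not None:
        kept, dropped = [], []
        for c in current:
            cts = cdna_cts.get(c.proxy_snp)
            if cts is None or filter_low_expression(c, cts, ct_cutoff, expression_fraction):
                kept.append(c)
            else:
                dropped.append((c, REASON_LOW_EXPRESSION))
        rep = _stage_report("low_expression", kept, dropped)
        excluded.extend(rep.excluded)
        stage_counts.update(rep.stage_counts)
        current = rep.selected

    rep = select_one_per_locus(current)
    excluded.extend(rep.excluded)
    stage_counts.update(rep.stage_counts)
    return SelectionReport(rep.selected, excluded, stage_counts)


def count_coding_lead_loci(candidates: Iterable[CandidateVariant]) -> int:
    """Number of loci whose primary lead SNP is itself a transcribed coding variant."""
    leads = {
        c.lead_snp
        for c in candidates
        if not c.is_secondary_signal
        and c.proxy_snp == c.lead_snp
        and c.annotation in {"synonymous", "missense"}
    }
    return len(leads)


# ---------------------------------------------------------------------------
# Candidate table I/O and the packaged worked-example fixture
# ---------------------------------------------------------------------------

_BOOL_COLS = ("is_secondary_signal", "in_inversion_region",
              "isoform_restricted", "assay_failed")


def candidates_from_frame(table: pd.DataFrame) -> list[CandidateVariant]:
    out = []
    for row in table.to_dict("records"):
        out.append(
            CandidateVariant(
                lead_snp=str(row["lead_snp"]),
                proxy_snp=str(row["proxy_snp"]),
                gene=str(row["gene"]),
                r2=float(row["r2"]),
                dprime=float(row["dprime"]),
                annotation=str(row["annotation"]),
                locus_id=str(row["locus_id"]),
                is_secondary_signal=_as_bool(row.get("is_secondary_signal", False)),
                in_inversion_region=_as_bool(row.get("in_inversion_region", False)),
                isoform_restricted=_as_bool(row.get("isoform_restricted", False)),
                assay_failed=_as_bool(row.get("assay_failed", False)),
                technology=(str(row["technology"]) or None)
                if not pd.isna(row.get("technology")) else None,
            )
        )
    return out


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes"}
    return bool(value)


def read_candidates(path: str | Path) -> list[CandidateVariant]:
    """Read a candidate table from TSV."""
    return candidates_from_frame(pd.read_csv(path, sep="\t"))


def write_candidates(candidates: Sequence[CandidateVariant], path: str | Path) -> None:
    pd.DataFrame([_as_dict(c) for c in candidates]).to_csv(path, sep="\t", index=False)


def load_candidate_fixture() -> list[CandidateVariant]:
    """The packaged worked-example candidate table.

    Reconstructed from a published selection of transcribed markers at
    Parkinson's disease GWAS loci: the thirteen marker/gene pairs that
    survived selection plus the candidates the study describes excluding
    (an unexpressed gene, an inversion-locus cluster, an isoform-restricted
    marker and a failed assay).  See the data file header for which fields
    are printed values and which are synthetic placeholders.
    """
    with resources.files("aseqpcr.data").joinpath("candidates.tsv").open() as fh:
        return candidates_from_frame(pd.read_csv(fh, sep="\t", comment="#"))


def load_fixture_expression_cts() -> dict[str, list[float]]:
    """cDNA Ct observations accompanying the packaged candidate table."""
    with resources.files("aseqpcr.data").joinpath("fixture_cdna_ct.csv").open() as fh:
        table = pd.read_csv(fh, comment="#")
    from aseqpcr.io import parse_ct_column

    table["ct"] = parse_ct_column(table["ct"])
    return {
        snp: grp["ct"].tolist()
        for snp, grp in table.groupby("proxy_snp")
    }
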