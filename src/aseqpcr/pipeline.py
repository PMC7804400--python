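"""End-to-end runs and publication-style output tables.

Ties the stages together -- marker selection, assay calibration, genotype
calling, allelic-expression statistics and cross-tissue comparison -- into
reproducible file-to-file runs, and renders the per-assay results in the
conventional column order (marker SNP, gene, heterozygote count, risk
allele, observed ASE direction, overall P value; blood tables add MAF).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from types import SimpleNamespace
from typing import Sequence

import pandas as pd

from aseqpcr import ase, calibration, genotyping, io, selection, simulate

logger = logging.getLogger("aseqpcr")

ASSAY_RESULT_COLUMNS = [
    "assay_id", "gene", "tissue", "maf", "n_het", "risk_allele",
    "direction_label", "risk_allele_direction", "overall_p", "ase_detected",
    "mean_n_delta_ct", "fold_change", "consistency", "diagnosis_p",
]

SAMPLE_RESULT_COLUMNS = [
    "sample_id", "assay_id", "tissue", "diagnosis", "n_replicates_used",
    "mean_delta_ct", "n_delta_ct", "fold_change", "p_value", "significant",
]


def assay_results_frame(results: Sequence[ase.AseAssayResult]) -> pd.DataFrame:
    rows = [
        {col: getattr(r, col) for col in ASSAY_RESULT_COLUMNS} for r in results
    ]
    return pd.DataFrame(rows, columns=ASSAY_RESULT_COLUMNS)


def sample_results_frame(results: Sequence[ase.AseAssayResult]) -> pd.DataFrame:
    rows = [
        {col: getattr(s, col) for col in SAMPLE_RESULT_COLUMNS}
        for r in results
        for s in r.sample_results
    ]
    return pd.DataFrame(rows, columns=SAMPLE_RESULT_COLUMNS)


def render_assay_table(
    results: Sequence[ase.AseAssayResult], include_maf: bool = False
) -> pd.DataFrame:
    """Publication-style per-assay table.

    P values are formatted in scientific notation with two significant
    digits; ``include_maf`` adds the minor-allele-frequency column used
    for blood replication tables.
    """
    columns = ["Transcribed SNP", "Gene"]
    if include_maf:
        columns.append("MAF")
    columns += ["Het. samples", "Risk allele", "Observed ASE", "Overall P value"]
    rows = []
    for r in results:
        row = {"Transcribed SNP": r.assay_id, "Gene": r.gene}
        if include_maf:
            row["MAF"] = "" if r.maf is None else f"{r.maf:.2f}"
        row.update(
            {"Het. samples": r.n_het, "Risk allele": r.risk_allele,
             "Observed ASE": r.direction_label,
             "Overall P value": f"{r.overall_p:.1e}"}
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def run_ase_stage(
    wells: pd.DataFrame,
    meta: pd.DataFrame,
    roster: pd.DataFrame,
    assays: pd.DataFrame,
    alpha: float = 0.05,
    ct_cutoff: float = 36.0,
    min_replicates: int = 3,
    comparator: str = "pooled",
) -> list[ase.AseAssayResult]:
    """Per-assay, per-tissue allelic-expression analysis over a cohort.

    ``roster`` is the heterozygote roster from genotype calling (columns
    assay_id, tissue, donor_id); both the gDNA and cDNA samples of each
    rostered donor enter the assay's analysis.
    """
    meta_ix = meta.drop_duplicates("sample_id").set_index("sample_id")
    results = []
    for assay_row in assays.to_dict("records"):
        assay_id = assay_row["assay_id"]
        assay_roster = roster[roster["assay_id"] == assay_id]
        for tissue in sorted(assay_roster["tissue"].unique()):
            donors = set(assay_roster.loc[assay_roster["tissue"] == tissue,
                                          "donor_id"])
            het_samples = [
                s for s in meta_ix.index
                if meta_ix.at[s, "donor_id"] in donors
                and meta_ix.at[s, "tissue"] == tissue
            ]
            maf = assay_row.get("maf")
            results.append(
                ase.analyze_assay(
                    wells, meta, het_samples, assay_row,
                    alpha=alpha, ct_cutoff=ct_cutoff,
                    min_replicates=min_replicates, comparator=comparator,
                    maf=float(maf) if maf not in (None, "") and not pd.isna(maf)
                    else None,
                )
            )
    return results


def compare_tissue_frames(
    brain: pd.DataFrame, blood: pd.DataFrame
) -> pd.DataFrame:
    """Cross-tissue classification from two per-assay result tables."""

    def as_results(frame: pd.DataFrame) -> list:
        return [
            SimpleNamespace(
                assay_id=row["assay_id"], gene=row["gene"],
                overall_p=float(row["overall_p"]),
                ase_detected=bool(row["ase_detected"]),
                mean_n_delta_ct=float(row["mean_n_delta_ct"]),
            )
            for row in frame.to_dict("records")
        ]

    return ase.compare_tissues(as_results(brain), as_results(blood))


@dataclass
class RunConfig:
    """File paths and parameters for a full pipeline run."""

    out_dir: Path
    candidates: Path | None = None
    cdna_ct: Path | None = None
    calibration_plate: Path | None = None
    gdna_plate: Path | None = None
    expression_plate: Path | None = None
    meta: Path | None = None
    assays: Path | None = None
    alpha: float = 0.05
    ct_cutoff: float = 36.0
    ld_threshold: float = 0.6
    min_replicates: int = 3
    slope_tol: float = 0.3
    r2_min: float = 0.9
    het_window: float = 1.5

    def validate(self) -> None:
        for name in ("candidates", "cdna_ct", "calibration_plate", "gdna_plate",
                     "expression_plate", "meta", "assays"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} input does not exist: {path}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage whose inputs are configured; write all outputs.

    Returns the run summary (also written as ``run_summary.json``), which
    echoes every parameter and reconciles per-stage counts.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "parameters": {
            "alpha": config.alpha, "ct_cutoff": config.ct_cutoff,
            "ld_threshold": config.ld_threshold,
            "min_replicates": config.min_replicates,
            "slope_tol": config.slope_tol, "r2_min": config.r2_min,
            "het_window": config.het_window,
        },
        "stages": {},
    }

    if config.candidates is not None:
        logger.info("stage select: %s", config.candidates)
        cands = selection.read_candidates(config.candidates)
        cts = None
        if config.cdna_ct is not None:
            ct_table = pd.read_csv(config.cdna_ct, comment="#")
            ct_table["ct"] = io.parse_ct_column(ct_table["ct"])
            cts = {s: g["ct"].tolist() for s, g in ct_table.groupby("proxy_snp")}
        report = selection.run_selection(
            cands, ld_threshold=config.ld_threshold,
            ct_cutoff=config.ct_cutoff, cdna_cts=cts,
        )
        report.to_frame().to_csv(out / "selection.tsv", sep="\t", index=False)
        (out / "selection_summary.json").write_text(report.summary_json())
        for cand, reason in report.excluded:
            logger.warning("excluded %s (%s): %s", cand.proxy_snp, cand.gene, reason)
        summary["stages"]["select"] = {
            "input": report.n_input, "selected": len(report.selected),
            "excluded": len(report.excluded),
            "genes": len(report.selected_genes),
        }

    if config.calibration_plate is not None:
        logger.info("stage calibrate: %s", config.calibration_plate)
        wells = io.read_plate_csv(config.calibration_plate)
        results = calibration.calibrate_plate(wells, config.slope_tol, config.r2_min)
        frame = pd.DataFrame([r.to_dict() for r in results])
        frame["reasons"] = frame["reasons"].map(";".join)
        frame.to_csv(out / "calibration.tsv", sep="\t", index=False)
        (out / "calibration.json").write_text(
            json.dumps([r.to_dict() for r in results], indent=2)
        )
        summary["stages"]["calibrate"] = {
            "assays": len(results),
            "passed": sum(r.passed for r in results),
        }

    roster = None
    if config.gdna_plate is not None:
        if config.meta is None:
            raise ValueError("genotype stage requires sample metadata")
        logger.info("stage genotype: %s", config.gdna_plate)
        wells = io.read_plate_csv(config.gdna_plate)
        meta = io.read_meta_csv(config.meta)
        calls, roster = genotyping.call_cohort(
            wells, meta, het_window=config.het_window,
            dropout_ct=config.ct_cutoff,
        )
        calls.to_csv(out / "genotype_calls.tsv", sep="\t", index=False)
        roster.to_csv(out / "het_roster.tsv", sep="\t", index=False)
        summary["stages"]["genotype"] = {
            "samples": int(calls[["sample_id"]].drop_duplicates().shape[0]),
            "calls": {k: int(v) for k, v in
                      calls["call"].value_counts().items()},
            "het_roster": int(len(roster)),
        }

    if config.expression_plate is not None:
        if config.meta is None or config.assays is None or roster is None:
            raise ValueError(
                "ase stage requires sample metadata, assay metadata and a "
                "genotype roster (run the genotype stage in the same config)"
            )
        logger.info("stage ase: %s", config.expression_plate)
        wells = io.read_plate_csv(config.expression_plate)
        meta = io.read_meta_csv(config.meta)
        assays = io.read_assay_metadata(config.assays)
        results = run_ase_stage(
            wells, meta, roster, assays, alpha=config.alpha,
            ct_cutoff=config.ct_cutoff, min_replicates=config.min_replicates,
        )
        assay_results_frame(results).to_csv(
            out / "ase_assays.tsv", sep="\t", index=False
        )
        sample_results_frame(results).to_csv(
            out / "ase_samples.tsv", sep="\t", index=False
        )
        tissues = sorted({r.tissue for r in results})
        for tissue in tissues:
            sub = [r for r in results if r.tissue == tissue]
            render_assay_table(sub, include_maf=(tissue == "blood")).to_csv(
                out / f"ase_table_{tissue}.tsv", sep="\t", index=False
            )
        summary["stages"]["ase"] = {
            "assays_analyzed": len(results),
            "ase_detected": sum(r.ase_detected for r in results),
        }
        if len(tissues) >= 2 and {"brain", "blood"} <= set(tissues):
            comparison = ase.compare_tissues(
                [r for r in results if r.tissue == "brain"],
                [r for r in results if r.tissue == "blood"],
            )
            comparison.to_csv(out / "tissue_comparison.tsv", sep="\t", index=False)
            summary["stages"]["compare"] = {
                k: int(v) for k, v in comparison["class"].value_counts().items()
            }

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_demo(seed: int, out_dir: str | Path) -> dict:
    """Simulation-to-report run requiring no external files.

    Simulates a two-assay cohort (one assay with a true two-fold allelic
    imbalance, one balanced) in brain and blood, writes the plates, then
    runs selection on the packaged worked example, calibration, genotyping
    and the allelic-expression analysis over the simulated plates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = simulate.SimulationConfig(
        seed=seed,
        n_donors=60,
        maf=0.4,
        true_fold_change={"ASSAY01": 2.0, "ASSAY02": 1.0},
        efficiency=1.0,
        dye_bias=0.4,
        noise_sd=0.15,
        tissues=("brain", "blood"),
        assay_ids=("ASSAY01", "ASSAY02"),
    )
    wells, meta, truth = simulate.simulate_study(config)
    io.write_plate_csv(wells, out / "plate_study.csv")
    io.write_meta_csv(meta, out / "samples.csv")
    truth.to_csv(out / "truth.csv", index=False)

    import numpy as np

    rng = np.random.default_rng(seed + 1)
    mix = pd.concat(
        [simulate.simulate_mixture_series(config=config, rng=rng, assay_id=a)
         for a in config.assay_ids],
        ignore_index=True,
    )
    io.write_plate_csv(mix, out / "plate_mixture.csv")

    gdna_samples = set(meta.loc[meta["material"] == "gDNA", "sample_id"])
    io.write_plate_csv(
        wells[wells["sample_id"].isin(gdna_samples)], out / "plate_gdna.csv"
    )

    assays = pd.DataFrame(
        {
            "assay_id": ["ASSAY01", "ASSAY02"],
            "gene": ["GENE1", "GENE2"],
            "risk_allele": ["A", "B"],
            "fam_allele": ["A", "A"],
            "vic_allele": ["B", "B"],
            "maf": [config.maf, config.maf],
        }
    )
    assays.to_csv(out / "assays.tsv", sep="\t", index=False)

    fixture_dir = out / "fixture"
    fixture_dir.mkdir(exist_ok=True)
    selection.write_candidates(selection.load_candidate_fixture(),
                               fixture_dir / "candidates.tsv")
    ct_rows = [
        {"proxy_snp": snp, "sample_id": f"S{i + 1:02d}", "ct": ct}
        for snp, cts in selection.load_fixture_expression_cts().items()
        for i, ct in enumerate(cts)
    ]
    pd.DataFrame(ct_rows).to_csv(fixture_dir / "cdna_ct.csv", index=False)

    run_config = RunConfig(
        out_dir=out,
        candidates=fixture_dir / "candidates.tsv",
        cdna_ct=fixture_dir / "cdna_ct.csv",
        calibration_plate=out / "plate_mixture.csv",
        gdna_plate=out / "plate_gdna.csv",
        expression_plate=out / "plate_study.csv",
        meta=out / "samples.csv",
        assays=out / "assays.tsv",
    )
    return run_pipeline(run_config)
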