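"""Generative model for allele-discrimination qPCR plates.

The simulator produces the three kinds of plate export consumed by the
analysis stages -- genomic-DNA genotyping plates, cDNA allelic-expression
plates and allele-mixture calibration series -- from an explicit
exponential-amplification measurement model:

    Ct = C0 - log2(q) / log2(1 + E) + delta * [dye == FAM] + eps,
    eps ~ Normal(0, sigma^2),

where ``q`` is the relative template quantity loaded for that dye's allele,
``E`` is the per-cycle amplification efficiency (E = 1 means perfect
doubling), ``delta`` is an additive dye bias on the FAM channel and ``C0``
is the Ct of one unit of template.  A reaction whose (noisy) Ct exceeds the
run's cycle limit never crosses threshold and is exported as
``Undetermined``; in memory a censored channel is ``NaN``.

Ground truth (per-donor genotypes, each assay's true allelic fold change
and its dye-to-allele orientation) is emitted alongside the plates so every
downstream stage can be certified against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FAM = "FAM"
VIC = "VIC"

#: The nine allele-mixture ratios of the standard sensitivity experiment,
#: expressed as FAM-allele : VIC-allele quantity ratios.
DEFAULT_MIXTURE_RATIOS: tuple[float, ...] = (
    4.0, 2.0, 1.5, 1.25, 1.0, 1 / 1.25, 1 / 1.5, 1 / 2, 1 / 4,
)

_PLATE_ROWS = "ABCDEFGHIJKLMNOP"
_PLATE_COLS = 24
_PLATE_SIZE = len(_PLATE_ROWS) * _PLATE_COLS  # 384


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the qPCR measurement and cohort model.

    Parameters
    ----------
    seed:
        Seed for the random generator; identical config + seed gives
        byte-identical output tables.
    n_donors:
        Number of donors in the simulated cohort.
    maf:
        Minor allele frequency of the marker SNP; genotypes follow
        Hardy-Weinberg proportions.
    case_fraction:
        Fraction of donors labelled as patients (the rest are controls).
    true_fold_change:
        True cDNA abundance ratio of the FAM-allele transcript to the
        VIC-allele transcript (phi).  A scalar applies to every assay;
        a mapping gives one phi per assay id.
    efficiency:
        Per-cycle amplification efficiency E in (0, 1], either one value
        for both dyes or a ``{"FAM": ..., "VIC": ...}`` mapping.
    dye_bias:
        Additive Ct offset applied to the FAM channel (models unequal
        amplification of the two allele probes).
    noise_sd:
        Replicate-to-replicate Ct standard deviation.
    baseline_ct:
        Ct of one unit of template quantity (C0).
    ct_max:
        Cycle limit of the run; Ct values beyond it are censored.
    """

    seed: int = 0
    n_donors: int = 60
    maf: float = 0.4
    case_fraction: float = 0.4
    true_fold_change: float | Mapping[str, float] = 1.0
    efficiency: float | Mapping[str, float] = 0.9
    dye_bias: float = 0.0
    noise_sd: float = 0.15
    baseline_ct: float = 24.0
    ct_max: float = 40.0
    n_replicates_cdna: int = 5
    n_replicates_gdna: int = 3
    tissues: tuple[str, ...] = ("brain",)
    assay_ids: tuple[str, ...] = ("ASSAY01",)

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf must be in [0, 1], got {self.maf}")
        if not 0.0 <= self.case_fraction <= 1.0:
            raise ValueError(f"case_fraction must be in [0, 1], got {self.case_fraction}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.ct_max <= 0:
            raise ValueError(f"ct_max must be positive, got {self.ct_max}")
        if self.n_donors < 0:
            raise ValueError("n_donors must be non-negative")
        for assay in self.assay_ids:
            phi = self.fold_change_for(assay)
            if not phi > 0:
                raise ValueError(f"true_fold_change must be positive, got {phi} for {assay}")
        for dye in (FAM, VIC):
            e = self.efficiency_for(dye)
            if not 0.0 < e <= 1.0:
                raise ValueError(f"efficiency must be in (0, 1], got {e} for {dye}")

    def fold_change_for(self, assay_id: str) -> float:
        if isinstance(self.true_fold_change, Mapping):
            return float(self.true_fold_change[assay_id])
        return float(self.true_fold_change)

    def efficiency_for(self, dye: str) -> float:
        if isinstance(self.efficiency, Mapping):
            return float(self.efficiency[dye])
        return float(self.efficiency)


def expected_ct(quantity: float, dye: str, config: SimulationConfig) -> float:
    """Noise-free Ct for a template quantity on one dye channel."""
    if not quantity > 0:
        raise ValueError(f"template quantity must be positive, got {quantity}")
    if dye not in (FAM, VIC):
        raise ValueError(f"dye must be 'FAM' or 'VIC', got {dye!r}")
    e = config.efficiency_for(dye)
    ct = config.baseline_ct - math.log2(quantity) / math.log2(1.0 + e)
    if dye == FAM:
        ct += config.dye_bias
    return ct


def simulate_ct(
    quantity: float,
    dye: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> float:
    """Draw one Ct measurement; returns ``NaN`` when censored at ``ct_max``.

    Raises ``ValueError`` for non-positive quantities: a zero-template
    reaction is not a measurement and callers emit ``Undetermined``
    directly for absent alleles.
    """
    ct = expected_ct(quantity, dye, config)
    if config.noise_sd > 0:
        ct += rng.normal(0.0, config.noise_sd)
    return float(ct) if ct <= config.ct_max else math.nan


def simulate_genotypes(
    n_donors: int,
    maf: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw genotypes under Hardy-Weinberg proportions.

    ``AA`` is the minor-allele homozygote (probability maf^2), ``AB`` the
    heterozygote (2 maf (1-maf)), ``BB`` the major-allele homozygote.
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"maf must be in [0, 1], got {maf}")
    if n_donors < 0:
        raise ValueError("n_donors must be non-negative")
    probs = np.array([maf**2, 2 * maf * (1 - maf), (1 - maf) ** 2])
    idx = rng.choice(3, size=n_donors, p=probs)
    return np.array(["AA", "AB", "BB"])[idx]


def _well_labels(start: int, count: int) -> tuple[list[str], list[str]]:
    """Sequential 384-well positions and plate ids from a running offset."""
    plates, wells = [], []
    for i in range(start, start + count):
        plate, pos = divmod(i, _PLATE_SIZE)
        row, col = divmod(pos, _PLATE_COLS)
        plates.append(f"P{plate + 1:02d}")
        wells.append(f"{_PLATE_ROWS[row]}{col + 1:02d}")
    return plates, wells


def _measure_channels(
    q_fam: np.ndarray,
    q_vic: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-channel measurement; q = 0 encodes an absent allele."""
    out = []
    for q, dye in ((q_fam, FAM), (q_vic, VIC)):
        q = np.asarray(q, dtype=float)
        e = config.efficiency_for(dye)
        with np.errstate(divide="ignore"):
            ct = config.baseline_ct - np.log2(np.where(q > 0, q, 1.0)) / math.log2(1.0 + e)
        if dye == FAM:
            ct = ct + config.dye_bias
        if config.noise_sd > 0:
            ct = ct + rng.normal(0.0, config.noise_sd, size=ct.shape)
        ct = np.where((q > 0) & (ct <= config.ct_max), ct, np.nan)
        out.append(ct)
    return out[0], out[1]


def _plate_frame(rows: dict, start: int) -> pd.DataFrame:
    n = len(rows["sample_id"])
    plates, wells = _well_labels(start, n)
    return pd.DataFrame(
        {
            "plate_id": plates,
            "well": wells,
            "sample_id": rows["sample_id"],
            "assay_id": rows["assay_id"],
            "replicate": rows["replicate"],
            "ct_fam": rows["ct_fam"],
            "ct_vic": rows["ct_vic"],
        }
    )


def _genotype_quantities(genotype: str, phi: float, material: str) -> tuple[float, float]:
    """Relative (FAM-allele, VIC-allele) template quantities for one sample.

    gDNA carries two allele copies in the genotype's proportions; cDNA from a
    heterozygote carries the alleles at the assay's true fold change phi,
    scaled to the same total template load.
    """
    if genotype == "AA":
        return 2.0, 0.0
    if genotype == "BB":
        return 0.0, 2.0
    if material == "gDNA":
        return 1.0, 1.0
    scale = 2.0 / (phi + 1.0)
    return phi * scale, scale


def simulate_study(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full ASE study: plates, sample metadata and ground truth.

    Returns ``(wells, meta, truth)``:

    - ``wells``: one row per replicate reaction with both channel Cts;
    - ``meta``: sample_id, donor_id, tissue, material, diagnosis;
    - ``truth``: per (donor, assay) genotype plus the assay's true fold
      change and dye orientation (FAM reads the minor ``A`` allele).
    """
    rng = np.random.default_rng(config.seed)
    donors = [f"D{i + 1:03d}" for i in range(config.n_donors)]
    n_cases = int(round(config.case_fraction * config.n_donors))
    diagnosis = {d: ("PD" if i < n_cases else "control") for i, d in enumerate(donors)}

    truth_rows = []
    genotypes: dict[str, np.ndarray] = {}
    for assay in config.assay_ids:
        g = simulate_genotypes(config.n_donors, config.maf, rng)
        genotypes[assay] = g
        phi = config.fold_change_for(assay)
        for donor, geno in zip(donors, g):
            truth_rows.append(
                {"donor_id": donor, "assay_id": assay, "genotype": geno,
                 "true_fold_change": phi, "fam_allele": "A", "vic_allele": "B"}
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["donor_id", "assay_id", "genotype", "true_fold_change",
                 "fam_allele", "vic_allele"],
    )

    meta_rows = []
    cols: dict[str, list] = {k: [] for k in
                             ("sample_id", "assay_id", "replicate", "q_fam", "q_vic")}
    for tissue in config.tissues:
        for material, n_rep in (("gDNA", config.n_replicates_gdna),
                                ("cDNA", config.n_replicates_cdna)):
            for donor in donors:
                sample_id = f"{donor}_{tissue}_{material}"
                meta_rows.append(
                    {"sample_id": sample_id, "donor_id": donor, "tissue": tissue,
                     "material": material, "diagnosis": diagnosis[donor]}
                )
                for assay_i, assay in enumerate(config.assay_ids):
                    geno = genotypes[assay][donors.index(donor)]
                    if material == "cDNA" and geno != "AB":
                        # only heterozygotes are taken forward to expression plates
                        continue
                    qf, qv = _genotype_quantities(
                        geno, config.fold_change_for(assay), material
                    )
                    for rep in range(1, n_rep + 1):
                        cols["sample_id"].append(sample_id)
                        cols["assay_id"].append(assay)
                        cols["replicate"].append(rep)
                        cols["q_fam"].append(qf)
                        cols["q_vic"].append(qv)

    q_fam = np.array(cols.pop("q_fam"), dtype=float)
    q_vic = np.array(cols.pop("q_vic"), dtype=float)
    ct_fam, ct_vic = _measure_channels(q_fam, q_vic, config, rng)
    cols["ct_fam"], cols["ct_vic"] = ct_fam, ct_vic
    wells = _plate_frame(cols, 0)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "donor_id", "tissue", "material", "diagnosis"]
    ).drop_duplicates("sample_id", ignore_index=True)
    return wells, meta, truth


def simulate_het_cohort(
    n_het: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    assay_id: str | None = None,
    tissue: str = "brain",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plates and metadata for a cohort of exactly ``n_het`` heterozygous donors.

    Convenience entry point for calibration studies of the ASE statistics
    (type-I error, power, fold-change recovery), where the number of
    informative donors is the design variable rather than MAF.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    assay = assay_id or config.assay_ids[0]
    phi = config.fold_change_for(assay)
    n_cases = int(round(config.case_fraction * n_het))

    meta_rows = []
    cols: dict[str, list] = {k: [] for k in
                             ("sample_id", "assay_id", "replicate", "q_fam", "q_vic")}
    for material, n_rep in (("gDNA", config.n_replicates_gdna),
                            ("cDNA", config.n_replicates_cdna)):
        for i in range(n_het):
            donor = f"D{i + 1:03d}"
            sample_id = f"{donor}_{tissue}_{material}"
            meta_rows.append(
                {"sample_id": sample_id, "donor_id": donor, "tissue": tissue,
                 "material": material,
                 "diagnosis": "PD" if i < n_cases else "control"}
            )
            qf, qv = _genotype_quantities("AB", phi, material)
            for rep in range(1, n_rep + 1):
                cols["sample_id"].append(sample_id)
                cols["assay_id"].append(assay)
                cols["replicate"].append(rep)
                cols["q_fam"].append(qf)
                cols["q_vic"].append(qv)

    q_fam = np.array(cols.pop("q_fam"), dtype=float)
    q_vic = np.array(cols.pop("q_vic"), dtype=float)
    cols["ct_fam"], cols["ct_vic"] = _measure_channels(q_fam, q_vic, config, rng)
    wells = _plate_frame(cols, 0)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "donor_id", "tissue", "material", "diagnosis"]
    )
    return wells, meta


def ratio_sample_id(ratio: float) -> str:
    """Instrument-style sample name for a mixture ratio, e.g. ``mix_4_1``."""
    if ratio >= 1:
        return f"mix_{ratio:g}_1"
    return f"mix_1_{1 / ratio:g}"


def parse_ratio_sample_id(sample_id: str) -> float | None:
    """Inverse of :func:`ratio_sample_id`; ``None`` for non-mixture samples."""
    parts = sample_id.split("_")
    if len(parts) != 3 or parts[0] != "mix":
        return None
    try:
        num, den = float(parts[1]), float(parts[2])
    except ValueError:
        return None
    if num <= 0 or den <= 0:
        return None
    return num / den


def simulate_mixture_series(
    ratios: Sequence[float] | None = None,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    assay_id: str | None = None,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate the allele-mixture sensitivity series for one assay.

    Each ratio ``r`` gives triplicate wells loaded with allele quantities
    ``(r*q, q)`` at constant total template, plus one heterozygous-control
    sample at an exact 1:1 ratio.
    """
    if config is None:
        config = SimulationConfig()
    if ratios is None:
        ratios = DEFAULT_MIXTURE_RATIOS
    if len(ratios) == 0:
        raise ValueError("at least one mixture ratio is required")
    for r in ratios:
        if not r > 0:
            raise ValueError(f"mixture ratios must be positive, got {r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    assay = assay_id or config.assay_ids[0]

    cols: dict[str, list] = {k: [] for k in
                             ("sample_id", "assay_id", "replicate", "q_fam", "q_vic")}
    entries = [(ratio_sample_id(r), r) for r in ratios] + [("het_control", 1.0)]
    for sample_id, r in entries:
        q = 2.0 / (1.0 + r)
        for rep in range(1, n_replicates + 1):
            cols["sample_id"].append(sample_id)
            cols["assay_id"].append(assay)
            cols["replicate"].append(rep)
            cols["q_fam"].append(r * q)
            cols["q_vic"].append(q)

    q_fam = np.array(cols.pop("q_fam"), dtype=float)
    q_vic = np.array(cols.pop("q_vic"), dtype=float)
    cols["ct_fam"], cols["ct_vic"] = _measure_channels(q_fam, q_vic, config, rng)
    return _plate_frame(cols, 0)
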