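"""Synthetic genotype and longitudinal-cohort generator.

Emulates a biennial population cohort in which each subject's trait follows a
linear trajectory in age: a subject-specific level (the value at the subject's
own mean age) and an annual change rate.  Both trajectory parameters carry
polygenic effects with a chosen genetic correlation, an optional extra
SNP-by-smoking genetic effect acts on the change rate of ever-smokers, and
visit-level measurement error is heteroscedastic across visits.  Because every
generating parameter is known, downstream trajectory extraction, GRM
construction, REML variance components and GWAS are all testable without any
restricted cohort data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimTruth",
    "GenotypeMatrix",
    "LongitudinalCohort",
    "simulate_genotypes",
    "simulate_cohort",
    "write_plink",
    "write_vcf",
    "write_phenotypes",
    "read_phenotypes",
]

SMOKING_LEVELS = ("never", "ever", "missing")


@dataclass(frozen=True)
class SimTruth:
    """Generating parameters for one synthetic cohort.

    ``h0_sq`` / ``h1_sq`` are the fractions of trajectory-level (intercept /
    slope) variance that are additive-genetic; ``rho_g`` / ``rho_e`` the
    genetic and residual correlations between the two trajectory parameters;
    ``gxe_var_frac`` the fraction of slope variance contributed, in
    ever-smokers only, by an independent second polygenic draw (the
    SNP-by-smoking interaction component).  Trajectory variances are
    normalised to 1; per-visit measurement noise is added on top.
    """

    n_subjects: int = 1000
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h0_sq: float = 0.3
    h1_sq: float = 0.15
    rho_g: float = 0.6
    rho_e: float = 0.1
    gxe_var_frac: float = 0.0
    smoker_frac: float = 0.4
    missing_smoking_frac: float = 0.0
    n_visits: int = 8
    visit_spacing_years: float = 2.0
    baseline_age_range: tuple[float, float] = (40.0, 69.0)
    visit_noise_sds: tuple[float, ...] | None = None
    dropout_prob: float = 0.1
    slope_sd: float = 0.07  # trait units / year; scales beta1 without touching h1_sq
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        for name in ("h0_sq", "h1_sq", "gxe_var_frac"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in ("rho_g", "rho_e"):
            v = getattr(self, name)
            if not (-1.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [-1, 1], got {v}")
        if self.h1_sq + self.gxe_var_frac >= 1.0:
            raise ValueError(
                "h1_sq + gxe_var_frac must be < 1 "
                f"(got {self.h1_sq} + {self.gxe_var_frac})"
            )
        if self.visit_noise_sds is not None:
            sds = np.asarray(self.visit_noise_sds, dtype=float)
            if sds.shape != (self.n_visits,):
                raise ValueError("visit_noise_sds must have length n_visits")
            if not np.all(sds > 0):
                raise ValueError("visit_noise_sds must be strictly positive")
            object.__setattr__(self, "visit_noise_sds", tuple(float(s) for s in sds))

    @property
    def noise_sds(self) -> np.ndarray:
        # default: measurement SD ~40% of the between-subject SD at every visit
        if self.visit_noise_sds is None:
            return np.full(self.n_visits, 0.4)
        return np.asarray(self.visit_noise_sds, dtype=float)


@dataclass
class GenotypeMatrix:
    """n x M additive dosage matrix (0..2, NaN = missing) with SNP metadata."""

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_alt: np.ndarray  # (M, 2) array: [ref, alt]; dosage counts alt copies
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        ok = np.isnan(self.dosages) | ((self.dosages >= 0) & (self.dosages <= 2))
        if not ok.all():
            raise ValueError("dosages must lie in [0, 2] or be NaN")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_alt=self.ref_alt[idx],
            sample_ids=self.sample_ids,
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            ref_alt=self.ref_alt,
            sample_ids=self.sample_ids[idx],
        )


@dataclass
class LongitudinalCohort:
    """Long-format visit records plus per-subject attributes.

    ``data`` columns: subject_id, visit (1-based), age, sex (0/1), height (cm),
    smoking ({never, ever, missing}) and one column per trait.  Within a
    subject, ages are strictly increasing and visit indices unique.
    """

    data: pd.DataFrame
    traits: list[str]

    def __post_init__(self) -> None:
        required = {"subject_id", "visit", "age", "sex", "height", "smoking"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort data missing columns: {sorted(missing)}")
        for t in self.traits:
            if t not in self.data.columns:
                raise ValueError(f"trait column {t!r} absent from cohort data")
        g = self.data.groupby("subject_id", sort=False)
        if (g["visit"].nunique() != g["visit"].size()).any():
            raise ValueError("visit index not unique within subject")
        if not g["age"].apply(lambda a: bool(np.all(np.diff(a.to_numpy()) > 0))).all():
            raise ValueError("ages not strictly increasing within subject")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    def subjects(self) -> pd.DataFrame:
        """One row per subject with time-constant attributes."""
        cols = ["subject_id", "sex", "height", "smoking"]
        return self.data[cols].drop_duplicates("subject_id").set_index("subject_id")

    def visit_counts(self) -> pd.Series:
        return self.data.groupby("subject_id", sort=False)["visit"].size()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def simulate_genotypes(truth: SimTruth) -> GenotypeMatrix:
    """Draw unlinked biallelic SNPs in Hardy-Weinberg proportions.

    Each SNP's generating allele frequency is uniform on ``truth.maf_range``
    and dosages are the sum of two Bernoulli(p) draws.  The generating
    frequencies are stashed on the result as ``gen_freq`` for effect-size
    standardisation in :func:`simulate_cohort`.
    """
    if truth.n_subjects < 2 or truth.n_snps < 1:
        raise ValueError("need n_subjects >= 2 and n_snps >= 1")
    rng = np.random.default_rng(truth.seed)
    n, m = truth.n_subjects, truth.n_snps
    p = rng.uniform(truth.maf_range[0], truth.maf_range[1], size=m)
    dos = (rng.random((n, m)) < p).astype(float) + (rng.random((n, m)) < p)
    geno = GenotypeMatrix(
        dosages=dos,
        snp_ids=np.array([f"snp{i + 1}" for i in range(m)]),
        chrom=np.array(["1"] * m),
        pos=np.arange(1, m + 1, dtype=int) * 1000,
        ref_alt=np.array([("A", "G")] * m),
        sample_ids=np.array([f"S{i + 1:05d}" for i in range(n)]),
    )
    geno.gen_freq = p  # type: ignore[attr-defined]
    return geno


def _standardize(dos: np.ndarray, p: np.ndarray) -> np.ndarray:
    return (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def simulate_cohort(
    truth: SimTruth, geno: GenotypeMatrix
) -> tuple[LongitudinalCohort, pd.DataFrame]:
    """Generate visit-level trait values on top of ``geno``.

    Per-SNP effect pairs on (intercept, slope) are bivariate normal with
    correlation ``rho_g``, scaled so the polygenic values have variances
    ``h0_sq`` and ``h1_sq`` of the unit trajectory variances; independent
    residual subject effects fill the remainder with correlation ``rho_e``.
    Ever-smokers receive an extra independent polygenic slope component with
    variance ``gxe_var_frac``.  Observed values are
    ``y_ij = b0 + b1 * (age_ij - mean(age_i)) + e_ij`` with per-visit noise
    SDs and independent per-visit dropout.

    Returns the cohort and a per-subject truth table with columns
    subject_id, g0, g1, gxe, beta0, beta1 (beta1 in trait units / year).
    """
    n, m = truth.n_subjects, truth.n_snps
    if geno.n_samples != n:
        raise ValueError("genotype matrix rows must equal n_subjects")
    if truth.h1_sq + truth.gxe_var_frac >= 1.0 or truth.h0_sq >= 1.0:
        raise ValueError("variance fractions must sum to < 1")
    rng = np.random.default_rng(truth.seed + 1)

    p = getattr(geno, "gen_freq", None)
    if p is None:
        p = geno.allele_freq
    z = _standardize(np.nan_to_num(geno.dosages, nan=0.0), p)

    # per-SNP effects: bivariate normal, var h0/M and h1/M, correlation rho_g
    cov = np.array(
        [
            [truth.h0_sq / m, truth.rho_g * np.sqrt(truth.h0_sq * truth.h1_sq) / m],
            [truth.rho_g * np.sqrt(truth.h0_sq * truth.h1_sq) / m, truth.h1_sq / m],
        ]
    )
    a = rng.multivariate_normal([0.0, 0.0], cov, size=m, method="svd")
    g0 = z @ a[:, 0]
    g1 = z @ a[:, 1]

    # smoking exposure, independent of genotype
    u = rng.random(n)
    smoking = np.where(u < truth.smoker_frac, "ever", "never")
    miss = rng.random(n) < truth.missing_smoking_frac
    smoking = np.where(miss, "missing", smoking)

    # GxE: independent SNP-effect draws per smoking group, so the slope's
    # genetic effect differs by exposure (cov sigma_gxe^2 * A within a group,
    # 0 across groups) -- the structure the interaction variance component
    # estimator models
    if truth.gxe_var_frac > 0:
        b_ever = rng.normal(0.0, np.sqrt(truth.gxe_var_frac / m), size=m)
        b_never = rng.normal(0.0, np.sqrt(truth.gxe_var_frac / m), size=m)
        gxe = np.where(smoking == "ever", z @ b_ever, z @ b_never)
    else:
        gxe = np.zeros(n)

    e_var0 = 1.0 - truth.h0_sq
    e_var1 = 1.0 - truth.h1_sq - truth.gxe_var_frac
    e_cov = truth.rho_e * np.sqrt(e_var0 * e_var1)
    ecovm = np.array([[e_var0, e_cov], [e_cov, e_var1]])
    e = rng.multivariate_normal([0.0, 0.0], ecovm, size=n, method="svd")

    beta0 = g0 + e[:, 0]
    beta1_std = g1 + gxe + e[:, 1]  # unit-variance scale
    beta1 = truth.slope_sd * beta1_std

    sex = (rng.random(n) < 0.5).astype(int)
    height = rng.normal(160.0, 6.0, size=n) + 8.0 * sex
    age0 = rng.uniform(*truth.baseline_age_range, size=n)

    noise_sds = truth.noise_sds
    keep = rng.random((n, truth.n_visits)) >= truth.dropout_prob

    rows: list[dict] = []
    eps = rng.normal(0.0, 1.0, size=(n, truth.n_visits)) * noise_sds[None, :]
    visit_offsets = np.arange(truth.n_visits) * truth.visit_spacing_years
    for i in range(n):
        obs = np.flatnonzero(keep[i])
        if obs.size == 0:
            continue
        ages = age0[i] + visit_offsets[obs]
        mean_age = ages.mean()
        y = beta0[i] + beta1[i] * (ages - mean_age) + eps[i, obs]
        for j, age, yv in zip(obs, ages, y):
            rows.append(
                {
                    "subject_id": geno.sample_ids[i],
                    "visit": int(j) + 1,
                    "age": float(age),
                    "sex": int(sex[i]),
                    "height": float(height[i]),
                    "smoking": smoking[i],
                    "y": float(yv),
                }
            )
    cohort = LongitudinalCohort(data=pd.DataFrame(rows), traits=["y"])
    truth_df = pd.DataFrame(
        {
            "subject_id": geno.sample_ids,
            "g0": g0,
            "g1": g1,
            "gxe": gxe,
            "beta0": beta0,
            "beta1": beta1,
            "beta1_std": beta1_std,
            "smoking": smoking,
        }
    )
    return cohort, truth_df


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------


def write_plink(geno: GenotypeMatrix, prefix: str) -> None:
    """Write variant-major PLINK .bed/.bim/.fam (dosage = alt-allele count)."""
    n, m = geno.n_samples, geno.n_snps
    with open(f"{prefix}.fam", "w") as f:
        for sid in geno.sample_ids:
            f.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(f"{prefix}.bim", "w") as f:
        for j in range(m):
            ref, alt = geno.ref_alt[j]
            f.write(f"{geno.chrom[j]}\t{geno.snp_ids[j]}\t0\t{geno.pos[j]}\t{alt}\t{ref}\n")
    # 2-bit codes, A1 = alt: 00 hom-alt(2), 10 het(1), 11 hom-ref(0), 01 missing
    code = np.full((m, n), 0b01, dtype=np.uint8)
    d = geno.dosages.T  # variant-major
    code[d == 2] = 0b00
    code[d == 1] = 0b10
    code[d == 0] = 0b11
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for k in range(4):
        cols = np.arange(k, n, 4)
        packed[:, : len(cols)] |= code[:, cols] << (2 * k)
    with open(f"{prefix}.bed", "wb") as f:
        f.write(bytes([0x6C, 0x1B, 0x01]))
        f.write(packed.tobytes())


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read variant-major PLINK .bed/.bim/.fam into a dosage matrix."""
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None)
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None, dtype={0: str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(f"{prefix}.bed", dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise ValueError(f"{prefix}.bed is not a variant-major PLINK bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    dos = np.empty((m, n), dtype=float)
    lookup = np.array([2.0, np.nan, 1.0, 0.0])  # 00, 01, 10, 11 with A1 = alt
    for k in range(4):
        cols = np.arange(k, n, 4)
        dos[:, cols] = lookup[(body[:, cols // 4] >> (2 * k)) & 0b11]
    return GenotypeMatrix(
        dosages=dos.T,
        snp_ids=bim[1].to_numpy(dtype=str),
        chrom=bim[0].to_numpy(dtype=str),
        pos=bim[3].to_numpy(dtype=int),
        ref_alt=np.stack([bim[5].to_numpy(dtype=str), bim[4].to_numpy(dtype=str)], axis=1),
        sample_ids=fam[1].to_numpy(dtype=str),
    )


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write hard-call genotypes as uncompressed VCF 4.2 with GT fields."""
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(geno.chrom)
        for c in chroms:
            f.write(f"##contig=<ID={c}>\n")
        f.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        f.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(geno.n_snps):
            ref, alt = geno.ref_alt[j]
            gts = [
                "./." if np.isnan(d) else gt_map[round(d)]
                for d in geno.dosages[:, j]
            ]
            f.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.snp_ids[j]}\t{ref}\t{alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF (via cyvcf2) into an alt-dosage matrix."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = np.array(vcf.samples)
    dos, ids, chrom, pos, alleles = [], [], [], [], []
    for var in vcf:
        # gts012 coding: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        arr = np.array(var.gt_types, dtype=float)
        arr[arr == 3] = np.nan
        dos.append(arr)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        alleles.append((var.REF, var.ALT[0] if var.ALT else "."))
    return GenotypeMatrix(
        dosages=np.array(dos).T,
        snp_ids=np.array(ids),
        chrom=np.array(chrom),
        pos=np.array(pos, dtype=int),
        ref_alt=np.array(alleles),
        sample_ids=samples,
    )


def write_phenotypes(cohort: LongitudinalCohort, path: str) -> None:
    cols = ["subject_id", "visit", "age", "sex", "height", "smoking"] + cohort.traits
    cohort.data[cols].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> LongitudinalCohort:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    fixed = {"subject_id", "visit", "age", "sex", "height", "smoking"}
    traits = [c for c in df.columns if c not in fixed]
    return LongitudinalCohort(data=df, traits=traits)
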