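"""Configuration-driven orchestration of the full analysis graph.

One entry point runs: synthetic-cohort generation (or reading of PLINK/VCF
genotypes plus a long-format phenotype table), per-subject trajectory
extraction, genotype QC and GRM construction, univariate / bivariate / GxE
variance-component fits per trait and smoking subgroup with FDR adjustment of
the heritability p-values across the trait family, and GWAS on the
transformed trajectory parameters.  Every run writes diff-able TSV outputs
plus a JSON manifest recording the config hash, the sample-count filter chain
and the output registry.
"""

from __future__ import annotations

import argparse
import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grm import compute_grm, grm_pca, qc_filter, write_grm_gcta
from .gwas import fdr_adjust, qq_manhattan_export, run_gwas
from .simdata import (
    GenotypeMatrix,
    LongitudinalCohort,
    SimTruth,
    read_phenotypes,
    read_plink,
    read_vcf,
    simulate_cohort,
    simulate_genotypes,
    write_phenotypes,
    write_plink,
)
from .stage1 import (
    estimate_visit_weights,
    fit_subject_trajectories,
    inverse_normal_transform,
    trajectories_frame,
)
from .varcomp import fit_bivariate_greml, fit_gxe_greml, fit_univariate_greml

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "subgroup_split", "main"]

log = logging.getLogger("longherit")

ALLOWED_SUBGROUPS = ("all", "never", "ever")

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_CONVERGENCE_ERROR = 4


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    # either simdata parameters or paths to real inputs
    simdata: dict | None = None
    genotypes: str | None = None  # PLINK prefix or .vcf path
    phenotypes: str | None = None  # long-format TSV
    traits: list[str] | None = None
    min_visits: int = 3
    weight_covariates: tuple[str, ...] = ("age", "sex", "height")
    subgroups: list[str] = field(default_factory=lambda: ["all"])
    univariate: bool = True
    bivariate: bool = True
    gxe: bool = False
    gwas: bool = False
    maf_min: float = 0.01
    missing_max: float = 0.05
    n_pcs: int = 10
    pcs_in_reml: bool = False
    reml_tol: float = 1e-6
    reml_max_iter: int = 100
    grm_mean_impute: bool = False

    def __post_init__(self) -> None:
        if not (self.univariate or self.bivariate or self.gxe or self.gwas):
            raise ValueError("at least one analysis must be enabled")
        bad = set(self.subgroups) - set(ALLOWED_SUBGROUPS)
        if bad:
            raise ValueError(f"unknown subgroup(s) {sorted(bad)}; allowed: {ALLOWED_SUBGROUPS}")
        if self.simdata is None and (self.genotypes is None or self.phenotypes is None):
            raise ValueError("provide either a simdata block or genotype+phenotype paths")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weight_covariates"] = list(self.weight_covariates)
        return d


@dataclass
class RunManifest:
    config_hash: str
    version: str
    counts: dict[str, int]
    outputs: dict[str, str]

    def write(self, path: Path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, sort_keys=True)
            f.write("\n")


def subgroup_split(
    cohort: LongitudinalCohort, spec: str, smoking_conditioned: bool = False
) -> LongitudinalCohort:
    """Subset the cohort by smoking status.

    ``never``/``ever`` select those groups (missing status always excluded);
    ``all`` keeps subjects with known status when ``smoking_conditioned`` is
    set (subgroup comparisons and interaction fits) and everyone otherwise.
    """
    if spec not in ALLOWED_SUBGROUPS:
        raise ValueError(f"unknown subgroup {spec!r}")
    df = cohort.data
    if spec == "all":
        sub = df if not smoking_conditioned else df[df["smoking"] != "missing"]
    else:
        sub = df[df["smoking"] == spec]
    if sub.empty:
        raise ValueError(f"subgroup {spec!r} is empty")
    return LongitudinalCohort(data=sub.reset_index(drop=True), traits=cohort.traits)


def _load_inputs(config: RunConfig) -> tuple[GenotypeMatrix, LongitudinalCohort]:
    if config.simdata is not None:
        truth = SimTruth(**{**config.simdata, "seed": config.simdata.get("seed", config.seed)})
        geno = simulate_genotypes(truth)
        cohort, _ = simulate_cohort(truth, geno)
        return geno, cohort
    gpath = config.genotypes
    geno = read_vcf(gpath) if str(gpath).endswith(".vcf") else read_plink(gpath)
    cohort = read_phenotypes(config.phenotypes)
    return geno, cohort


def _reml_design(
    traj: pd.DataFrame, subjects: pd.DataFrame, pcs: np.ndarray | None
) -> np.ndarray:
    """Fixed effects: intercept, sex, mean age, mean height (+ optional PCs)."""
    sub = subjects.loc[traj["subject_id"]]
    cols = [
        np.ones(len(traj)),
        sub["sex"].to_numpy(dtype=float),
        traj["mean_age"].to_numpy(dtype=float),
        sub["height"].to_numpy(dtype=float),
    ]
    X = np.column_stack(cols)
    if pcs is not None:
        X = np.column_stack([X, pcs])
    return X


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> RunManifest:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    outputs: dict[str, str] = {}
    counts: dict[str, int] = {}

    def register(name: str, path: Path) -> None:
        outputs[name] = str(path)

    geno, cohort = _load_inputs(config)
    subjects = cohort.subjects()
    counts["subjects_read"] = len(subjects)
    counts["subjects_smoking_known"] = int((subjects["smoking"] != "missing").sum())
    vc = cohort.visit_counts()
    counts["subjects_min_visits"] = int((vc >= config.min_visits).sum())
    log.info(
        "cohort: %d subjects read, %d with known smoking status, %d with >= %d visits",
        counts["subjects_read"], counts["subjects_smoking_known"],
        counts["subjects_min_visits"], config.min_visits,
    )

    traits = config.traits or cohort.traits
    traj_by_trait: dict[str, pd.DataFrame] = {}
    for trait in traits:
        weights = estimate_visit_weights(cohort, trait, config.weight_covariates)
        trajs = fit_subject_trajectories(cohort, trait, weights, config.min_visits)
        tf = trajectories_frame(trajs)
        traj_by_trait[trait] = tf
        weights.to_frame().to_csv(out / f"weights_{trait}.tsv", sep="\t", index=False)
        tf.to_csv(out / f"trajectories_{trait}.tsv", sep="\t", index=False)
        register(f"weights_{trait}", out / f"weights_{trait}.tsv")
        register(f"trajectories_{trait}", out / f"trajectories_{trait}.tsv")
    if stop_after == "stage1":
        return _finish(config, counts, outputs, out)

    geno_qc, qc_report = qc_filter(geno, config.maf_min, config.missing_max)
    log.info(
        "QC: %d SNPs in, %d removed by MAF, %d by missingness, %d kept",
        qc_report.n_snps_in, qc_report.n_removed_maf,
        qc_report.n_removed_missing, qc_report.n_snps_out,
    )
    with open(out / "qc_report.json", "w") as f:
        json.dump(dataclasses.asdict(qc_report), f, indent=2)
    register("qc_report", out / "qc_report.json")

    grm_full = compute_grm(geno_qc, mean_impute=config.grm_mean_impute)
    write_grm_gcta(grm_full, str(out / "cohort"))
    register("grm", out / "cohort.grm.bin")
    sample_index = {s: i for i, s in enumerate(grm_full.sample_ids)}
    if stop_after == "grm":
        manifest = _finish(config, counts, outputs, out)
        return manifest

    pcs_all = None
    if config.gwas or config.pcs_in_reml:
        k = min(config.n_pcs, grm_full.n - 1)
        pcs_all, _, _ = grm_pca(grm_full, k=k)
        pc_df = pd.DataFrame(pcs_all, columns=[f"PC{i + 1}" for i in range(k)])
        pc_df.insert(0, "subject_id", grm_full.sample_ids)
        pc_df.to_csv(out / "pcs.tsv", sep="\t", index=False)
        register("pcs", out / "pcs.tsv")

    uni_rows, bivar_rows, gxe_rows = [], [], []
    varcomp_json: dict[str, list[dict]] = {"univariate": [], "bivariate": [], "gxe": []}
    for sg in config.subgroups:
        sub_cohort = subgroup_split(cohort, sg, smoking_conditioned=(sg != "all"))
        sub_ids = set(sub_cohort.subject_ids)
        for trait in traits:
            tf = traj_by_trait[trait]
            tfs = tf[tf["subject_id"].isin(sub_ids)].reset_index(drop=True)
            if len(tfs) < 3:
                raise ValueError(f"subgroup {sg!r}: too few subjects with trajectories")
            idx = np.array([sample_index[s] for s in tfs["subject_id"]])
            grm_sub = grm_full.take(idx)
            # INT within the analysed sample: ranks are internal to each run
            y0 = inverse_normal_transform(tfs["beta0"].to_numpy())
            y1 = inverse_normal_transform(tfs["beta1"].to_numpy())
            pcs_sub = pcs_all[idx] if (config.pcs_in_reml and pcs_all is not None) else None
            X = _reml_design(tfs, subjects, pcs_sub)
            counts[f"n_used_{sg}_{trait}"] = len(tfs)

            if config.univariate:
                for name, y in (("h0", y0), ("h1", y1)):
                    res = fit_univariate_greml(
                        y, X, grm_sub, tol=config.reml_tol, max_iter=config.reml_max_iter
                    )
                    uni_rows.append(
                        {
                            "subgroup": sg, "trait": trait, "parameter": name,
                            "sigma_g2": res.sigma_g2, "sigma_e2": res.sigma_e2,
                            "h2": res.h2, "se_h2": res.se_h2, "lrt": res.lrt,
                            "p_value": res.p_value, "n": res.n_used,
                            "converged": res.converged,
                        }
                    )
                    varcomp_json["univariate"].append(
                        {"subgroup": sg, "trait": trait, "parameter": name,
                         **dataclasses.asdict(res)}
                    )
            if config.bivariate:
                b = fit_bivariate_greml(
                    y0, y1, X, grm_sub, tol=config.reml_tol,
                    max_iter=config.reml_max_iter,
                )
                from .varcomp import derived_quantities

                gcov, gcond = derived_quantities(b)
                bivar_rows.append(
                    {
                        "subgroup": sg, "trait": trait,
                        "sigma_g0_2": b.sigma_g0_2, "sigma_g1_2": b.sigma_g1_2,
                        "genetic_covariance": gcov, "rho_g": b.rho_g,
                        "se_rho_g": b.se_rho_g, "p_rho_g": b.p_rho_g,
                        "rho_e": b.rho_e, "se_rho_e": b.se_rho_e,
                        "conditional_slope_var": gcond, "n": b.n_used,
                        "converged": b.converged,
                    }
                )
                varcomp_json["bivariate"].append(
                    {"subgroup": sg, "trait": trait, **dataclasses.asdict(b)}
                )
            if config.gxe and sg == "all":
                smoking = subjects.loc[tfs["subject_id"], "smoking"].to_numpy()
                known = smoking != "missing"
                env = (smoking == "ever").astype(float)
                env[~known] = np.nan
                Xg = np.column_stack([X, np.where(known, env, 0.0)])
                for name, y in (("h0", y0), ("h1", y1)):
                    res = fit_gxe_greml(
                        np.where(known, y, np.nan), Xg, grm_sub, env,
                        tol=config.reml_tol, max_iter=config.reml_max_iter,
                    )
                    gxe_rows.append(
                        {
                            "subgroup": sg, "trait": trait, "parameter": name,
                            "sigma_g2": res.sigma_g2, "sigma_gxe2": res.sigma_gxe2,
                            "sigma_e2": res.sigma_e2, "h_gxe2": res.h_gxe2,
                            "se": res.se_h_gxe2, "p_value": res.p_value,
                            "n": res.n_used, "converged": res.converged,
                        }
                    )
                    varcomp_json["gxe"].append(
                        {"subgroup": sg, "trait": trait, "parameter": name,
                         **dataclasses.asdict(res)}
                    )

    if uni_rows:
        uni = pd.DataFrame(uni_rows)
        # FDR family: traits within one estimator type and subgroup
        uni["q_value"] = np.nan
        for (sg, par), grp in uni.groupby(["subgroup", "parameter"]):
            uni.loc[grp.index, "q_value"] = fdr_adjust(grp["p_value"].to_numpy())
        uni.to_csv(out / "heritability.tsv", sep="\t", index=False)
        register("heritability", out / "heritability.tsv")
        if not uni["converged"].all():
            log.warning("some univariate REML fits did not converge")
    if bivar_rows:
        pd.DataFrame(bivar_rows).to_csv(out / "bivariate.tsv", sep="\t", index=False)
        register("bivariate", out / "bivariate.tsv")
    if gxe_rows:
        gx = pd.DataFrame(gxe_rows)
        gx["q_value"] = np.nan
        for (sg, par), grp in gx.groupby(["subgroup", "parameter"]):
            gx.loc[grp.index, "q_value"] = fdr_adjust(grp["p_value"].to_numpy())
        gx.to_csv(out / "gxe.tsv", sep="\t", index=False)
        register("gxe", out / "gxe.tsv")
    if any(varcomp_json.values()):
        with open(out / "varcomp.json", "w") as f:
            json.dump(varcomp_json, f, indent=2, sort_keys=True, default=float)
            f.write("\n")
        register("varcomp_json", out / "varcomp.json")

    if config.gwas:
        for trait in traits:
            tf = traj_by_trait[trait]
            idx = np.array([sample_index[s] for s in tf["subject_id"]])
            geno_sub = geno_qc.take_samples(idx)
            covars = _reml_design(tf, subjects, pcs_all[idx])[:, 1:]  # drop intercept
            for name, col in (("beta0", "beta0"), ("beta1", "beta1")):
                y = inverse_normal_transform(tf[col].to_numpy())
                summ = run_gwas(y, geno_sub, covars)
                path = out / f"gwas_{trait}_{name}.tsv"
                summ.rows.to_csv(path, sep="\t", index=False, float_format="%.6g")
                register(f"gwas_{trait}_{name}", path)
                qq = qq_manhattan_export(summ)
                qq_path = out / f"gwas_{trait}_{name}_qq.tsv"
                qq[["snp_id", "cum_pos", "neglog10_p", "expected_neglog10_p"]].to_csv(
                    qq_path, sep="\t", index=False, float_format="%.6g"
                )
                register(f"gwas_{trait}_{name}_qq", qq_path)
                log.info(
                    "GWAS %s/%s: lambda = %.3f, %d genome-wide significant",
                    trait, name, summ.lambda_gc, summ.n_signif_gw,
                )

    return _finish(config, counts, outputs, out)


def _finish(
    config: RunConfig, counts: dict[str, int], outputs: dict[str, str], out: Path
) -> RunManifest:
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        version=__version__,
        counts=counts,
        outputs=outputs,
    )
    manifest.write(out / "manifest.json")
    return manifest


def _setup_logging(out: Path) -> None:
    if log.handlers:
        return
    log.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(fmt)
    log.addHandler(fh)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

_COMMANDS = ("simulate", "stage1", "grm", "reml", "gwas", "all")


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="longherit",
        description="Two-stage SNP heritability of longitudinal trait trajectories",
    )
    sub = parser.add_subparsers(dest="command", required=True)
    for cmd in _COMMANDS:
        p = sub.add_parser(cmd)
        p.add_argument("--config", required=True, help="YAML/JSON run configuration")
    args = parser.parse_args(argv)
    try:
        config = RunConfig.from_file(args.config)
        if args.command == "reml":
            config = dataclasses.replace(config, gwas=False)
        elif args.command == "gwas":
            config = dataclasses.replace(
                config, univariate=False, bivariate=False, gxe=False, gwas=True
            )
    except (OSError, TypeError, ValueError, yaml.YAMLError) as exc:
        print(f"config error: {exc}", file=sys.stderr)
        return EXIT_CONFIG_ERROR
    stop_after = args.command if args.command in ("stage1", "grm") else None
    try:
        if args.command == "simulate":
            _cli_simulate(config)
        else:
            run_pipeline(config, stop_after=stop_after)
    except ValueError as exc:
        print(f"data error: {exc}", file=sys.stderr)
        return EXIT_DATA_ERROR
    except RuntimeError as exc:
        print(f"convergence error: {exc}", file=sys.stderr)
        return EXIT_CONVERGENCE_ERROR
    return 0


def _cli_simulate(config: RunConfig) -> None:
    if config.simdata is None:
        raise ValueError("simulate requires a simdata block in the config")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = SimTruth(**{**config.simdata, "seed": config.simdata.get("seed", config.seed)})
    geno = simulate_genotypes(truth)
    cohort, truth_df = simulate_cohort(truth, geno)
    write_plink(geno, str(out / "sim"))
    write_phenotypes(cohort, str(out / "phenotypes.tsv"))
    truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)


if __name__ == "__main__":
    raise SystemExit(main())
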