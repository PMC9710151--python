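"""End-to-end experiment orchestration.

One experiment simulates a large (CEU-like) and a small (YRI-like)
population, generates a family of phenotypes (four per risk-SNP count), and
runs the three arms per phenotype — no-transfer baseline, SNP transfer, deep
transfer — then assembles the per-group comparison tables with the pooled
t-test.

Every stochastic step derives its seed deterministically from the master
seed, so a rerun with the same config reproduces the same reports.  Results
are cached per phenotype (``<code>/results.json``) and a rerun resumes from
the cache; resuming against a changed config is refused.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import popsim
from .classic_ml import run_small_baseline, run_snp_transfer
from .deep_transfer import (ArchitectureSpec, TrainingConfig, sweep_and_select,
                            train_source)
from .evaluate import build_comparison_table
from .harmonize import (FinalHoldout, LabeledSplit, SplitSpec,
                        intersect_common_snps, make_splits, qc_filter)
from .io_formats import (PhenotypeTable, write_gen, write_phenotype,
                         write_rsid_list)
from .preselect import (build_subdataset_ladder, geometric_thresholds,
                        materialize, score_snps)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preselect", "baseline", "snp-transfer", "deep-transfer",
          "evaluate")


def _seed32(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one full experiment."""

    # population model
    n_snps: int = 1000
    divergence_F: tuple[float, float] = (0.075, 0.075)
    ld_rho: float = 0.2
    private_snp_fraction: float = 0.3
    # cohorts and splits
    n_large: int = 1000
    n_small: int = 100
    n_final: int = 50
    large_split: tuple[int, int, int] = (700, 100, 200)
    small_split: tuple[int, int, int] = (70, 10, 20)
    # phenotypes
    risk_snp_counts: tuple[int, ...] = (5, 10)
    n_iterations: int = 4
    heritability: float = 0.5
    # pre-selection ladders (None -> geometric defaults)
    thresholds: tuple[float, ...] | None = None
    n_rungs_small: int = 13
    n_rungs_large: int = 10
    # deep transfer grid
    architectures: tuple[int, ...] = tuple(range(1, 10))
    freeze_plan_ts: tuple[int, ...] | None = None
    source_epochs: int = 50
    tune_epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    # misc
    master_seed: int = 0
    snp_transfer_refit: bool = False

    def phenotype_codes(self) -> list[tuple[int, int]]:
        return [(k, it) for k in self.risk_snp_counts
                for it in range(1, self.n_iterations + 1)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        for key in ("divergence_F", "large_split", "small_split",
                    "risk_snp_counts", "architectures"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        for key in ("thresholds", "freeze_plan_ts"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def scaled_study_config(master_seed: int = 0, heritability: float = 0.6,
                        **overrides) -> ExperimentConfig:
    """A scaled-down version of the full study, sized for a single CPU.

    Keeps the published cohort sizes (1000 large / 100 small / 50 final,
    splits 700/100/200 and 70/10/20) on a 1000-SNP panel, and reduces the
    search grid to 3 pre-selection rungs, 3 architectures (two dense, one
    recurrent) and 3 freeze plans at 20 epochs.
    """
    params = dict(
        n_snps=1000, n_large=1000, n_small=100, n_final=50,
        heritability=heritability,
        n_rungs_small=3, n_rungs_large=3,
        architectures=(1, 2, 4), freeze_plan_ts=(0, 1, 2),
        source_epochs=20, tune_epochs=20,
        master_seed=master_seed,
    )
    params.update(overrides)
    return ExperimentConfig(**params)


@dataclass
class PhenotypeRun:
    """Everything one phenotype's arms need: cohorts, splits, ladders."""

    code: str
    spec_small: popsim.PhenotypeSpec
    spec_large: popsim.PhenotypeSpec
    large_splits: dict[str, LabeledSplit]
    small_splits: dict[str, LabeledSplit]
    fd_split: LabeledSplit
    small_ladder: list
    large_ladder: list
    seeds: dict[str, int]
    large_cohort: popsim.SimulatedCohort = field(repr=False, default=None)
    small_cohort: popsim.SimulatedCohort = field(repr=False, default=None)


def prepare_phenotype(config: ExperimentConfig, k: int, it: int) -> PhenotypeRun:
    """Simulate, harmonize, split and pre-select for one phenotype code."""
    ss = np.random.SeedSequence([config.master_seed, k, it])
    names = ("structure", "genotypes", "pheno_large", "pheno_small", "fd",
             "split_large", "split_small", "effects", "ml")
    seeds = {n: _seed32(s) for n, s in zip(names, ss.spawn(len(names)))}

    model = popsim.PopulationModel.default(
        n_snps=config.n_snps,
        seed=seeds["structure"],
        divergence_F=config.divergence_F,
        ld_rho=config.ld_rho,
        private_snp_fraction=config.private_snp_fraction,
    )
    large_geno, small_geno = popsim.simulate_population_pair(
        model, config.n_large, config.n_small, seeds["genotypes"])

    spec = popsim.PhenotypeSpec.draw(
        popsim.shared_rsids(model), k, seeds["effects"],
        heritability=config.heritability, phenotype_code=f"YRI_{k}_{it}")
    spec_large = spec.with_population("CEU")

    large_cohort = popsim.simulate_phenotype(large_geno, spec_large,
                                             seeds["pheno_large"])
    small_cohort = popsim.simulate_phenotype(small_geno, spec,
                                             seeds["pheno_small"])

    large_qc, _ = qc_filter(large_cohort.genotypes)
    small_qc, _ = qc_filter(small_cohort.genotypes)
    large_h, small_h, _ = intersect_common_snps(large_qc, small_qc)
    large_cohort = dataclasses.replace(large_cohort, genotypes=large_h)
    small_cohort = dataclasses.replace(small_cohort, genotypes=small_h)

    large_splits = make_splits(
        large_cohort, SplitSpec(*config.large_split, seed=seeds["split_large"]))
    small_splits = make_splits(
        small_cohort, SplitSpec(*config.small_split, seed=seeds["split_small"]))

    fd_cohort = popsim.generate_fresh_cohort(model, spec, config.n_final,
                                             seeds["fd"])
    common = [r for r in large_h.rsids if r in set(fd_cohort.genotypes.rsids)]
    fd_split = LabeledSplit(fd_cohort.genotypes.subset_snps(common),
                            fd_cohort.binary_phenotype)

    def _ladder(splits, n_rungs, pop):
        scores = score_snps(splits["TD"].genotypes, splits["TD"].labels)
        thr = list(config.thresholds) if config.thresholds is not None \
            else geometric_thresholds(scores, n_rungs)
        return build_subdataset_ladder(scores, thr, source_population=pop)

    return PhenotypeRun(
        code=f"{k}_{it}",
        spec_small=spec,
        spec_large=spec_large,
        large_splits=large_splits,
        small_splits=small_splits,
        fd_split=fd_split,
        small_ladder=_ladder(small_splits, config.n_rungs_small, "YRI"),
        large_ladder=_ladder(large_splits, config.n_rungs_large, "CEU"),
        seeds=seeds,
        large_cohort=large_cohort,
        small_cohort=small_cohort,
    )


def run_deep_transfer(config: ExperimentConfig, run: PhenotypeRun):
    """Source training on every (rung, architecture), then the freeze sweep."""
    source_cfg = TrainingConfig(epochs=config.source_epochs,
                                batch_size=config.batch_size,
                                learning_rate=config.learning_rate,
                                seed=run.seeds["ml"])
    tune_cfg = dataclasses.replace(source_cfg, epochs=config.tune_epochs)
    source_models = []
    for sub in run.large_ladder:
        mats = materialize(sub, run.large_splits)
        for model_id in config.architectures:
            arch = ArchitectureSpec(model_id=model_id, input_dim=sub.n_snps)
            source_models.append(
                train_source(arch, mats["TD"], mats["VD"], source_cfg,
                             subdataset=sub))
    plans = list(config.freeze_plan_ts) if config.freeze_plan_ts is not None else None
    return sweep_and_select(source_models, run.small_splits,
                            FinalHoldout(run.fd_split), plans=plans,
                            config=tune_cfg)


def run_phenotype(config: ExperimentConfig, k: int, it: int) -> dict:
    """All three arms for one phenotype; returns the report row dict."""
    run = prepare_phenotype(config, k, it)
    baseline = run_small_baseline(run.small_splits, FinalHoldout(run.fd_split),
                                  run.small_ladder, seed=run.seeds["ml"])
    snp = run_snp_transfer(run.large_splits, run.small_splits,
                           FinalHoldout(run.fd_split), run.large_ladder,
                           seed=run.seeds["ml"],
                           refit_on_target=config.snp_transfer_refit)
    deep = run_deep_transfer(config, run)
    return {
        "code": run.code,
        "no_transfer": baseline.fd_accuracy,
        "snp_transfer": snp.fd_accuracy,
        "deep_transfer": deep.fd_accuracy,
        "detail": {
            "baseline": {"subdataset": baseline.best_subdataset.name,
                         "model": baseline.best_model.kind,
                         "ed_accuracy": baseline.ed_accuracy},
            "snp_transfer": {"subdataset": snp.best_subdataset.name,
                             "model": snp.best_model.kind,
                             "ed_accuracy": snp.ed_accuracy},
            "deep_transfer": {"subdataset": deep.best_subdataset.name,
                              "model": f"Model {deep.best_arch.model_id}",
                              "trainable_layers": deep.best_plan.t,
                              "ed_accuracy": deep.ed_accuracy},
        },
    }


def write_phenotype_files(config: ExperimentConfig, k: int, it: int,
                          outdir: str | Path) -> Path:
    """Emit the experiment directory for one phenotype: GEN/SAMPLE, phenotype
    files and per-rung rsid lists, following the <POP>_<K>_<iter> layout."""
    run = prepare_phenotype(config, k, it)
    out = Path(outdir)
    for pop, cohort in (("CEU", run.large_cohort), ("YRI", run.small_cohort)):
        d = out / f"{pop}_{k}_{it}"
        d.mkdir(parents=True, exist_ok=True)
        pheno = cohort.phenotype_table()
        write_gen(cohort.genotypes, d / f"{pop}.gen", d / f"{pop}.sample",
                  phenotype=pheno)
        write_phenotype(PhenotypeTable(pheno), d / f"{pop}.pheno")
        ladder = run.large_ladder if pop == "CEU" else run.small_ladder
        for sub in ladder:
            sub_dir = d / sub.name
            sub_dir.mkdir(exist_ok=True)
            write_rsid_list(list(sub.snp_ids), sub_dir / "rsids.txt")
        if pop == "YRI":
            for sub in run.large_ladder:
                sub_dir = d / f"snps_transfer_{sub.n_snps}"
                sub_dir.mkdir(exist_ok=True)
                write_rsid_list(list(sub.snp_ids), sub_dir / "rsids.txt")
    return out


def run_pipeline(config: ExperimentConfig, outdir: str | Path,
                 write_data_files: bool = False) -> dict:
    """Run every phenotype and build the per-group comparison tables.

    Per-phenotype results are cached in ``<outdir>/YRI_<k>_<it>/results.json``
    and reused on rerun; a cached directory whose stored config differs from
    the current one is refused.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_path = out / "config.json"
    current = json.dumps(config.to_dict(), sort_keys=True, indent=1)
    if cfg_path.exists():
        if cfg_path.read_text() != current:
            raise RuntimeError(
                f"{out} holds partial results for a different config; "
                "use a fresh output directory or restore the config")
    else:
        cfg_path.write_text(current)

    results: dict[str, dict] = {}
    for k, it in config.phenotype_codes():
        code = f"{k}_{it}"
        cache = out / f"YRI_{code}" / "results.json"
        if cache.exists():
            logger.info("phenotype %s: cached, skipping", code)
            results[code] = json.loads(cache.read_text())
            continue
        logger.info("phenotype %s: running (seed material %s/%s/%s)", code,
                    config.master_seed, k, it)
        if write_data_files:
            write_phenotype_files(config, k, it, out)
        row = run_phenotype(config, k, it)
        cache.parent.mkdir(parents=True, exist_ok=True)
        cache.write_text(json.dumps(row, indent=1))
        results[code] = row

    tables = {}
    for k in config.risk_snp_counts:
        group = {c: r for c, r in results.items() if c.startswith(f"{k}_")}
        if len(group) >= 2:
            table = build_comparison_table(
                {c: {a: r[a] for a in ("no_transfer", "snp_transfer",
                                       "deep_transfer")}
                 for c, r in group.items()})
            tables[k] = table
            table.table.to_csv(out / f"comparison_{k}_risk_snps.csv")
            (out / f"ttest_{k}_risk_snps.txt").write_text(
                f"t = {table.ttest.t:.4f}\ndf = {table.ttest.df}\n"
                f"se_diff = {table.ttest.se_diff:.3f}\n"
                f"p_two_tailed = {table.ttest.p_two_tailed:.4f}\n")
    return {"results": results, "tables": tables}
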