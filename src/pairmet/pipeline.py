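"""End-to-end orchestration: markers -> mechanism -> harmonize -> split ->
quantile-normalize -> k-TSP -> evaluation.

The pipeline runs either from a simulation configuration (the tested path)
or from on-disk cohort files. Every stage error is re-raised with the stage
name; all randomness flows from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import io as pio
from .datatypes import BulkCohort, SimTruth, SingleCellMatrix
from .hurdle import FDR_MAX, rank_markers
from .ktsp import DEFAULT_K_GRID, KTSP, KTSPResults
from .mechanism import MechanismPairSet, build_mechanism
from .prep import DEFAULT_STRATA, harmonize, quantile_normalize, stratified_split
from .simulate import (
    SimConfig,
    simulate_bulk_cohort,
    simulate_single_cell,
    simulate_survival,
)


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage
        self.cause = err


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; validated before any computation."""

    sim: SimConfig | None = None
    sc_dir: str | None = None        # on-disk single-cell input (alternative to sim)
    bulk_expr: str | None = None
    bulk_meta: str | None = None
    signature_clusters: list[str] = field(default_factory=lambda: ["c5", "c6", "c7"])
    n_top: int = 100
    fdr_max: float = FDR_MAX
    train_frac: float = 0.75
    strata_vars: list[str] = field(default_factory=lambda: list(DEFAULT_STRATA))
    k: int | None = 13
    k_grid: list[int] = field(default_factory=lambda: list(DEFAULT_K_GRID))
    folds: int = 5
    tie_class: int = 1
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.sim is None and (self.bulk_expr is None or self.bulk_meta is None):
            raise ValueError("config needs either a simulation block or bulk paths")
        if self.sim is not None:
            self.sim.validate()
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")
        if self.k is not None and (self.k < 1 or self.k % 2 == 0):
            raise ValueError("k must be an odd positive integer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = pio.read_yaml(path)
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            if sim == "default_study":
                cfg.sim = SimConfig.default_study(seed=cfg.seed)
            elif sim == "null_study":
                cfg.sim = SimConfig.null_study(seed=cfg.seed)
            else:
                sim.setdefault("seed", cfg.seed)
                sim["planted_markers"] = [
                    tuple(m) for m in sim.get("planted_markers", [])
                ]
                sim["planted_pairs"] = [
                    tuple(p) for p in sim.get("planted_pairs", [])
                ]
                sim["clusters"] = [tuple(c) for c in sim.get("clusters", [])] or None
                if sim["clusters"] is None:
                    sim.pop("clusters")
                cfg.sim = SimConfig(**sim)
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as err:
                raise StageError(name, err) from err
        return wrapped
    return deco


@_stage("inputs")
def _load_inputs(
    config: PipelineConfig,
) -> tuple[SingleCellMatrix | None, BulkCohort, SimTruth | None]:
    if config.sim is not None:
        sc, _ = simulate_single_cell(config.sim)
        bulk, truth = simulate_bulk_cohort(config.sim)
        bulk = simulate_survival(bulk, config.sim)
        return sc, bulk, truth
    bulk = pio.read_bulk_cohort(
        config.bulk_expr, config.bulk_meta, require_survival=True
    )
    sc = pio.read_single_cell(config.sc_dir) if config.sc_dir else None
    return sc, bulk, None


@_stage("markers")
def _markers(sc: SingleCellMatrix, clusters: list[str]) -> dict[str, pd.DataFrame]:
    present = set(sc.clusters())
    tables = {}
    for c in clusters:
        if c not in present:
            raise KeyError(f"signature cluster {c!r} absent from single-cell labels")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tables[c] = rank_markers(sc, c)
    return tables


@dataclass
class PipelineResult:
    """Everything a run produced, for reporting and recovery checks."""

    report: ev.EvaluationReport
    ktsp: KTSPResults
    mechanism: MechanismPairSet
    marker_tables: dict[str, pd.DataFrame]
    train: BulkCohort
    test: BulkCohort
    truth: SimTruth | None
    predictions: pd.DataFrame

    def recovered_pairs(self) -> set[tuple[str, str]]:
        """Planted pairs present in the selected signature (simulation runs)."""
        if self.truth is None:
            return set()
        selected = {(p.up_gene, p.down_gene) for p in self.ktsp.pairs}
        return selected & self.truth.pair_set()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; returns the report and all intermediates."""
    config.validate()
    sc, bulk, truth = _load_inputs(config)

    if sc is not None:
        marker_tables = _markers(sc, config.signature_clusters)
        mech = _stage("mechanism")(build_mechanism)(
            marker_tables, n_top=config.n_top, fdr_max=config.fdr_max
        )
    else:
        raise StageError(
            "mechanism", ValueError("no single-cell input to derive markers from")
        )
    if mech.pooled.empty:
        raise StageError("mechanism", ValueError("mechanism pair set is empty"))

    harmonized = _stage("harmonize")(harmonize)(bulk.split_by_dataset())
    train, test = _stage("split")(stratified_split)(
        harmonized, config.train_frac, config.strata_vars, seed=config.seed
    )
    train = BulkCohort(quantile_normalize(train.expr), train.meta)
    test = BulkCohort(quantile_normalize(test.expr), test.meta)

    model = KTSP(train, mech, tie_class=config.tie_class)
    results = _stage("ktsp")(model.fit)(
        k=config.k, k_grid=config.k_grid, folds=config.folds, seed=config.seed
    )

    vf_train, cls_train = results.predict(train)
    vf_test, cls_test = results.predict(test)
    y_train = train.meta["met_event"].to_numpy(dtype=int)
    y_test = test.meta["met_event"].to_numpy(dtype=int)
    auroc_train = ev.auroc(vf_train, y_train)
    auroc_test = ev.auroc(vf_test, y_test)

    # Logistic probability scoring on the signature genes, fit on training
    # expression only and applied unchanged to the test partition.
    genes = results.genes
    coef, _ = _stage("logistic")(ev.fit_logistic)(
        train.expr[genes].to_numpy(), y_train, ridge=1.0
    )
    X_test = test.expr[genes].to_numpy()
    logits = coef[0] + X_test @ coef[1:]
    probs = 1.0 / (1.0 + np.exp(-logits))
    pred_class = (probs >= 0.5).astype(int)

    report = ev.EvaluationReport(
        auroc_train=auroc_train,
        auroc_test=auroc_test,
        signature=results.signature_table(),
        extra={
            "k": results.k,
            "n_train": train.n_samples,
            "n_test": test.n_samples,
            "n_mechanism_pairs": int(mech.n_pairs),
            "seed": config.seed,
        },
    )

    surv_ok = (
        test.meta["pfs_months"].notna().all()
        and test.meta["pfs_event"].notna().all()
    )
    groups = np.where(cls_test == 1, "predicted_met", "predicted_nonmet")
    if surv_ok and len(np.unique(cls_test)) == 2 and test.meta["pfs_event"].sum() > 0:
        times = test.meta["pfs_months"].to_numpy()
        events = test.meta["pfs_event"].to_numpy(dtype=int)
        report.km_curves = _stage("kaplan_meier")(ev.kaplan_meier)(
            times, events, groups
        )
        report.logrank_stat, report.logrank_p = _stage("logrank")(ev.logrank)(
            times, events, groups
        )
        design = ev.gleason_dummies(test.meta["gleason"])
        design.insert(0, "predicted_class", cls_test.astype(float))
        try:
            report.survival_fit = _stage("cox")(ev.cox_ph)(design, times, events)
        except StageError as err:  # monotone likelihood on small cohorts
            report.extra["cox_error"] = str(err)

    predictions = pd.DataFrame(
        {
            "sample_id": list(train.sample_ids) + list(test.sample_ids),
            "partition": ["train"] * train.n_samples + ["test"] * test.n_samples,
            "vote_fraction": np.concatenate([vf_train, vf_test]),
            "predicted_class": np.concatenate([cls_train, cls_test]),
            "met_event": np.concatenate([y_train, y_test]),
        }
    )

    result = PipelineResult(
        report=report,
        ktsp=results,
        mechanism=mech,
        marker_tables=marker_tables,
        train=train,
        test=test,
        truth=truth,
        predictions=predictions,
    )
    if config.out_dir:
        _write_outputs(config, result)
    return result


def _write_outputs(config: PipelineConfig, result: PipelineResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.ktsp.signature_table().to_csv(
        out / "signature.tsv", sep="\t", index=False
    )
    result.predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
    result.report.to_json(out / "report.json")
    for cluster, table in result.marker_tables.items():
        table.to_csv(out / f"markers_{cluster}.tsv", sep="\t", index=False)
    result.mechanism.entries.to_csv(out / "mechanism.tsv", sep="\t", index=False)
    if result.truth is not None:
        pio.write_truth(result.truth, out / "truth.json")
    log = {
        "seed": config.seed,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "versions": _versions(),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)


def _versions() -> dict[str, str]:
    import lifelines
    import numpy
    import pandas
    import scipy
    import sklearn

    from . import __version__

    return {
        "pairmet": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "sklearn": sklearn.__version__,
        "lifelines": lifelines.__version__,
    }
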