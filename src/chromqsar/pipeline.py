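"""End-to-end 3D-QSAR pipeline orchestration and report statistics.

`run_pipeline` chains: read → annotate → align → grid → fields →
descriptor assembly → LOO component selection → PLS fit → validation
(training R², LOO Q², external-test Q²/R², RMSE) → field contributions →
contour maps → SAR-effect table, writing a serialized model, report
JSON/TSV and contour grids under a run directory.
`recompute_supplementary_stats` recomputes the headline statistics from a
predicted-vs-experimental activity table alone, with both R² modes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .contours import (
    SAR_FIELDS,
    classify_compound_effects,
    export_contour_set,
    extract_contours,
    stdev_coeff_values,
)
from .dataset import (
    ActivityRecord,
    MoleculeRecord,
    Split,
    annotate_atoms,
    derive_pmic,
    read_activity_table,
    read_structures,
)
from .fields import (
    DescriptorMatrix,
    FieldKind,
    FieldParams,
    assemble_descriptor_matrix,
    build_grid,
    compute_field_matrices,
)
from .pharmacophore import align_molecule, read_reference_hypothesis
from .pls import (
    PLSModel,
    external_q2,
    field_contributions,
    fit_pls,
    loo_cross_validate,
    predict_activity,
    regression_stats,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ValidationReport", "run_pipeline", "run_on_records", "recompute_supplementary_stats"]


@dataclass
class PipelineConfig:
    structures: str | Path | None = None
    activities: str | Path | None = None
    reference_hypothesis: str | Path | None = None
    output_dir: str | Path = "qsar_run"
    field_params: FieldParams = dc_field(default_factory=FieldParams)
    max_components: int | None = None
    r2_mode: str = "determination"
    favorable_percentile: float = 80.0
    unfavorable_percentile: float = 20.0
    filter_sd: float = 0.01
    pmic_basis: str = "molar"
    organism: str | None = None
    sar_threshold: float = 0.1
    allow_embed: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML mapping; unknown keys are rejected,
        ``field_params`` entries override the defaults."""
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        fp_overrides = doc.pop("field_params", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**doc)
        if fp_overrides:
            config.field_params = dataclasses.replace(FieldParams(), **fp_overrides)
        return config

    def effective_dict(self) -> dict:
        """The fully resolved configuration, for logging/auditing."""
        d = dataclasses.asdict(self)
        d["field_params"] = dataclasses.asdict(self.field_params)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


@dataclass
class ValidationReport:
    r2_train: float
    q2_loo: float
    q2_test: float | None
    r2_test: float | None
    rmse_train: float
    rmse_test: float | None
    n_components: int
    n_train: int
    n_test: int
    field_contributions: dict[str, float]
    q2_by_components: dict[int, float]
    predicted_vs_experimental: pd.DataFrame

    def to_dict(self) -> dict:
        d = {
            "r2_train": self.r2_train,
            "q2_loo": self.q2_loo,
            "q2_test": self.q2_test,
            "r2_test": self.r2_test,
            "rmse_train": self.rmse_train,
            "rmse_test": self.rmse_test,
            "n_components": self.n_components,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "field_contributions": self.field_contributions,
            "q2_by_components": {str(k): v for k, v in self.q2_by_components.items()},
        }
        return d


def run_pipeline(config: PipelineConfig) -> ValidationReport:
    """Run the full analysis from files on disk per the config."""
    molecules = read_structures(config.structures, allow_embed=config.allow_embed)
    molecules = [annotate_atoms(m) for m in molecules]
    activities = read_activity_table(config.activities, pmic_basis=config.pmic_basis)
    if config.organism is not None:
        from .dataset import parse_organism

        org = parse_organism(config.organism)
        activities = [a for a in activities if a.organism == org]
    activities = derive_pmic(activities, molecules, basis=config.pmic_basis)
    if config.reference_hypothesis is not None:
        reference = read_reference_hypothesis(config.reference_hypothesis)
        aligned = []
        for mol in molecules:
            try:
                amol, res = align_molecule(mol, reference)
                logger.info("aligned %s: feature RMSD %.3f Å", mol.id, res.feature_rmsd)
                aligned.append(amol)
            except ValueError as exc:
                raise ValueError(f"alignment stage failed for {mol.id!r}: {exc}") from exc
        molecules = aligned
    return run_on_records(molecules, activities, config)


def run_on_records(
    molecules: Sequence[MoleculeRecord],
    activities: Sequence[ActivityRecord],
    config: PipelineConfig | None = None,
) -> ValidationReport:
    """Run grid → fields → PLS → validation → contours on in-memory records.

    Molecules must already share a common frame. Censored activities never
    reach the regression; the grid is defined by training molecules only.
    """
    config = config or PipelineConfig()
    params = config.field_params
    by_id = {m.id: m for m in molecules}
    usable = [a for a in activities if not a.censored and a.pmic is not None and a.compound_id in by_id]
    n_censored = sum(1 for a in activities if a.censored)
    if n_censored:
        logger.info("excluded %d censored activity records from modelling", n_censored)
    train = [a for a in usable if a.split is not Split.TEST]
    test = [a for a in usable if a.split is Split.TEST]
    if len(train) < 4:
        raise ValueError(f"need at least 4 training activities, got {len(train)}")

    train_mols = [by_id[a.compound_id] for a in train]
    grid = build_grid(train_mols, params)
    outside = [
        m.id for a in test for m in [by_id[a.compound_id]] if not bool(grid.contains(m.coords).all())
    ]
    if outside:
        logger.warning("test molecules extend outside the training grid: %s", sorted(set(outside)))

    train_fields = compute_field_matrices(train_mols, grid, params)
    dm = assemble_descriptor_matrix(train_fields, filter_sd=config.filter_sd, grid=grid)
    y_train = np.array([a.pmic for a in train])

    cv = loo_cross_validate(dm, y_train, config.max_components)
    model = fit_pls(dm, y_train, cv.selected_components)
    yhat_train = predict_activity(model, dm)
    r2_train, rmse_train = regression_stats(y_train, yhat_train, config.r2_mode)
    contribs = field_contributions(model, dm)

    rows = [
        {
            "compound_id": a.compound_id,
            "organism": a.organism.value,
            "split": "train",
            "experimental_pmic": a.pmic,
            "predicted_pmic": float(yhat_train[i]),
        }
        for i, a in enumerate(train)
    ]

    q2_test = r2_test = rmse_test = None
    x_test = None
    if test:
        test_mols = [by_id[a.compound_id] for a in test]
        test_fields = compute_field_matrices(test_mols, grid, params)
        x_test = dm.transform(test_fields)
        y_test = np.array([a.pmic for a in test])
        yhat_test = predict_activity(model, x_test)
        if len(test) >= 2:
            q2_test = external_q2(y_test, yhat_test, float(y_train.mean()))
            r2_test, rmse_test = regression_stats(y_test, yhat_test, config.r2_mode)
        else:
            logger.info("single test compound: external statistics left undefined")
            rmse_test = float(np.sqrt(np.mean((y_test - yhat_test) ** 2)))
        rows.extend(
            {
                "compound_id": a.compound_id,
                "organism": a.organism.value,
                "split": "test",
                "experimental_pmic": a.pmic,
                "predicted_pmic": float(yhat_test[i]),
            }
            for i, a in enumerate(test)
        )

    report = ValidationReport(
        r2_train=r2_train,
        q2_loo=cv.q2_by_components[cv.selected_components],
        q2_test=q2_test,
        r2_test=r2_test,
        rmse_train=rmse_train,
        rmse_test=rmse_test,
        n_components=cv.selected_components,
        n_train=len(train),
        n_test=len(test),
        field_contributions={k.value: v for k, v in contribs.items()},
        q2_by_components=cv.q2_by_components,
        predicted_vs_experimental=pd.DataFrame(rows),
    )

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_artifacts(out_dir, config, model, dm, report, train, test, x_test)
    return report


def _write_artifacts(
    out_dir: Path,
    config: PipelineConfig,
    model: PLSModel,
    dm: DescriptorMatrix,
    report: ValidationReport,
    train: Sequence[ActivityRecord],
    test: Sequence[ActivityRecord],
    x_test: np.ndarray | None,
) -> None:
    sc = stdev_coeff_values(model, dm)
    contours = extract_contours(sc, dm, config.favorable_percentile, config.unfavorable_percentile)
    contour_dir = out_dir / "contours"
    for cs in contours.values():
        export_contour_set(cs, sc, dm, contour_dir)

    sar_rows = []
    for i, a in enumerate(train):
        row = classify_compound_effects(a.compound_id, dm.X[i], dm, contours, config.sar_threshold)
        sar_rows.append(row)
    if x_test is not None:
        for i, a in enumerate(test):
            sar_rows.append(
                classify_compound_effects(a.compound_id, x_test[i], dm, contours, config.sar_threshold)
            )
    sar_df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in sar_rows],
            **{
                f"{kind.value}_effect": [r.labels[kind].value for r in sar_rows]
                for kind in SAR_FIELDS
            },
        }
    )
    sar_df.to_csv(out_dir / "sar_table.tsv", sep="\t", index=False)

    report.predicted_vs_experimental.to_csv(
        out_dir / "predicted_vs_experimental.tsv", sep="\t", index=False, float_format="%.6f"
    )
    (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    (out_dir / "model.json").write_text(serialize_model(model, dm))
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "field_params": dataclasses.asdict(config.field_params),
        "filter_sd": config.filter_sd,
        "r2_mode": config.r2_mode,
        "pmic_basis": config.pmic_basis,
        "outputs": sorted(p.name for p in out_dir.iterdir()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def serialize_model(model: PLSModel, dm: DescriptorMatrix) -> str:
    """Serialize the fitted model and its preprocessing to one JSON doc."""
    doc = {
        "package_version": __version__,
        "n_components": model.n_components,
        "coefficients": model.coefficients.tolist(),
        "intercept": model.intercept,
        "x_weights": model.x_weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "x_means": model.x_means.tolist(),
        "y_mean": model.y_mean,
        "column_meta": [[kind.value, gidx] for kind, gidx in dm.column_meta],
        "column_means": dm.column_means.tolist(),
        "block_scales": {k.value: v for k, v in dm.block_scales.items()},
        "filter_sd": dm.filter_sd,
    }
    return json.dumps(doc, sort_keys=True)


# ---------------------------------------------------------------------------
# supplementary-statistics recomputation

_DEFAULT_COLMAP = {
    "experimental": "experimental_pmic",
    "predicted": "predicted_pmic",
    "split": "split",
    "organism": "organism",
}


def recompute_supplementary_stats(
    table: str | Path | pd.DataFrame,
    organism: str | None = None,
    colmap: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Recompute R²/Q²/RMSE from a predicted-vs-experimental table alone.

    Returns training R² in both modes (coefficient of determination and
    squared Pearson), external-test Q², and train/test RMSE; no refitting.
    ``colmap`` maps the roles {experimental, predicted, split, organism}
    onto the table's actual column names.
    """
    cols = dict(_DEFAULT_COLMAP)
    if colmap:
        cols.update(colmap)
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep=None, engine="python")
    for role in ("experimental", "predicted", "split"):
        if cols[role] not in df.columns:
            raise ValueError(f"table is missing the {role!r} column ({cols[role]!r})")
    if organism is not None:
        if cols["organism"] not in df.columns:
            raise ValueError(f"table is missing the organism column ({cols['organism']!r})")
        from .dataset import parse_organism

        org = parse_organism(organism)
        df = df[df[cols["organism"]].map(lambda s: parse_organism(s) == org)]

    split = df[cols["split"]].astype(str).str.strip().str.lower()
    train = df[split == "train"]
    test = df[split == "test"]
    if len(train) < 2:
        raise ValueError("fewer than 2 training rows")
    y_tr = train[cols["experimental"]].to_numpy(float)
    yhat_tr = train[cols["predicted"]].to_numpy(float)
    r2_det, rmse_tr = regression_stats(y_tr, yhat_tr, "determination")
    r2_pear, _ = regression_stats(y_tr, yhat_tr, "pearson")
    out = {
        "r2_train": r2_det,
        "r2_train_pearson": r2_pear,
        "rmse_train": rmse_tr,
        "n_train": int(len(train)),
        "n_test": int(len(test)),
    }
    if len(test) >= 2:
        y_te = test[cols["experimental"]].to_numpy(float)
        yhat_te = test[cols["predicted"]].to_numpy(float)
        out["q2_test"] = external_q2(y_te, yhat_te, float(y_tr.mean()))
        r2_te_det, rmse_te = regression_stats(y_te, yhat_te, "determination")
        r2_te_pear, _ = regression_stats(y_te, yhat_te, "pearson")
        out["r2_test"] = r2_te_det
        out["r2_test_pearson"] = r2_te_pear
        out["rmse_test"] = rmse_te
    return out
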