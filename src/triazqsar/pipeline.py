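"""End-to-end orchestration: structures -> activities -> fields -> PLS -> maps.

``run_pipeline`` executes the full study with one config object whose
defaults reproduce the in-house modelling run: the 25-compound MDA-MB231
dataset, the published 19/6 split, Gasteiger charges, a 2 A grid with 4 A
margin, +/-30 kcal/mol truncation, 50/50 field weights and LOO-q2 component
selection.  Every stage logs to stderr and the run ends with a JSON manifest
(config, seed, library versions, sha256 digests of all artifacts) so two runs
with the same config and seed are byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity, contours, fields, library, pls, prep

logger = logging.getLogger("triazqsar")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "prepare_descriptors"]


@dataclass
class RunConfig:
    """Flat, serializable pipeline configuration (defaults = the study run)."""

    seed: int = 2020
    n_starts: int = 20
    charge_scheme: str = "gasteiger"  # gasteiger | mmff
    reference_id: int = 101  # alignment reference: most active compound
    grid_spacing: float = 2.0  # Angstrom
    grid_margin: float = 4.0  # Angstrom
    truncation: float = 30.0  # kcal/mol
    steric_weight: float = 0.5
    electrostatic_weight: float = 0.5
    variance_floor: float = 1e-6
    split_mode: str = "explicit"  # explicit | diverse
    test_ids: tuple[int, ...] = activity.DEFAULT_TEST_IDS
    n_test: int = 6
    # Fixed component count (the convention of fixed-component CoMFA protocols);
    # set to 0 to pick the count by leave-one-out q2 capped at max_components.
    n_components: int = 5
    max_components: int = 5
    contour_low_pct: float = 20.0
    contour_high_pct: float = 80.0
    cell_line: str = "MDA-MB231"
    viability_threshold: float = 50.0
    override_ids: tuple[int, ...] = activity.DEFAULT_OVERRIDE_IDS

    def field_config(self) -> fields.FieldConfig:
        return fields.FieldConfig(
            truncation=self.truncation,
            steric_weight=self.steric_weight,
            electrostatic_weight=self.electrostatic_weight,
            variance_floor=self.variance_floor,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["test_ids"] = list(d["test_ids"])
        d["override_ids"] = list(d["override_ids"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("test_ids", "override_ids"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class PipelineResult:
    config: RunConfig
    records: list
    dataset: activity.QsarDataset
    alignment: prep.AlignmentResult
    descriptors: fields.DescriptorMatrix
    split: pls.SplitAssignment
    model: pls.PlsModel
    report: pls.ModelReport
    contour_sets: list
    manifest: dict | None = None


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def prepare_descriptors(
    config: RunConfig, compound_ids, records_by_id
) -> tuple[prep.AlignmentResult, fields.DescriptorMatrix]:
    """Conformers, charges, alignment and field grids for the given ids."""
    confs = []
    for cid in compound_ids:
        conf = prep.embed_minimize(
            records_by_id[cid].mol, compound_id=cid, seed=config.seed, n_starts=config.n_starts
        )
        confs.append(prep.assign_charges(conf, scheme=config.charge_scheme))
    reference = config.reference_id if config.reference_id in set(compound_ids) else None
    alignment = prep.align_to_reference(confs, reference_id=reference)
    grid = fields.make_grid(
        alignment.conformers, spacing=config.grid_spacing, margin=config.grid_margin
    )
    fc = config.field_config()
    blocks = [fields.compute_field_block(c, grid, fc) for c in alignment.conformers]
    descriptors = fields.assemble_descriptor_matrix(blocks, grid, fc)
    return alignment, descriptors


def run_pipeline(config: RunConfig | None = None, outdir=None) -> PipelineResult:
    """Execute every stage; write artifacts and a manifest when outdir given."""
    config = config or RunConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    records = _stage("build-library")(library.build_library)()
    by_id = {r.id: r for r in records}

    @_stage("prepare-activities")
    def _activities():
        viability = activity.load_viability()
        potency = activity.load_potency()
        ids = activity.select_actives(
            viability,
            cell_line=config.cell_line,
            threshold_pct=config.viability_threshold,
            include_override=config.override_ids,
        )
        return activity.build_qsar_dataset(potency, ids, cell_line=config.cell_line)

    dataset = _activities()

    alignment, descriptors = _stage("align+fields")(prepare_descriptors)(
        config, dataset.ids, by_id
    )

    @_stage("fit")
    def _fit():
        if config.split_mode == "explicit":
            split = pls.diverse_split(dataset, explicit_test=config.test_ids)
        elif config.split_mode == "diverse":
            split = pls.diverse_split(
                dataset, n_test=config.n_test, seed=config.seed, X=descriptors.X
            )
        else:
            raise ValueError(f"unknown split_mode {config.split_mode!r}")
        train_rows = [descriptors.compound_ids.index(cid) for cid in split.train_ids]
        X_train = descriptors.X[train_rows]
        y_train = np.array([dict(dataset.entries)[cid] for cid in split.train_ids])
        if config.n_components:
            k = config.n_components
        else:
            k = pls.choose_components(X_train, y_train, config.max_components)
        model = pls.fit_pls(X_train, y_train, k)
        X_by_id = {cid: descriptors.row_for(cid) for cid in dataset.ids}
        report = pls.residual_table(dataset, split, model, X_by_id)
        return split, model, report, X_train

    split, model, report, X_train = _fit()

    @_stage("contours")
    def _contours():
        return [
            contours.build_contour_set(
                model, descriptors, X_train, ftype,
                config.contour_low_pct, config.contour_high_pct,
            )
            for ftype in ("steric", "electrostatic")
        ]

    contour_sets = _contours()

    result = PipelineResult(
        config=config,
        records=records,
        dataset=dataset,
        alignment=alignment,
        descriptors=descriptors,
        split=split,
        model=model,
        report=report,
        contour_sets=contour_sets,
    )
    if out is not None:
        result.manifest = _write_artifacts(result, out)
    return result


def report_frame(report: pls.ModelReport) -> pd.DataFrame:
    return pd.DataFrame(report.rows)


def report_stats(report: pls.ModelReport) -> dict:
    return {
        "n_components": report.n_components,
        "r2_train": report.r2_train,
        "rmse_train": report.rmse_train,
        "r2_ss_train": report.r2_ss_train,
        "r2_test": report.r2_test,
        "rmse_test": report.rmse_test,
        "r2_pooled": report.r2_pooled,
        "rmse_pooled": report.rmse_pooled,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@_stage("write-artifacts")
def _write_artifacts(result: PipelineResult, out: Path) -> dict:
    library.write_structures(result.records, out / "structures.smi", fmt="smi")
    result.dataset.to_frame().assign(
        split=[
            "test" if cid in set(result.split.test_ids) else "train"
            for cid in result.dataset.ids
        ]
    ).to_csv(out / "dataset.tsv", sep="\t", index=False)
    prep.write_aligned_sdf(result.alignment.conformers, out / "aligned.sdf")
    pd.DataFrame(
        {
            "compound_id": list(result.alignment.scaffold_rmsd),
            "scaffold_rmsd": list(result.alignment.scaffold_rmsd.values()),
        }
    ).to_csv(out / "alignment.tsv", sep="\t", index=False)

    desc = result.descriptors
    pd.DataFrame(
        desc.X,
        index=pd.Index(desc.compound_ids, name="compound_id"),
        columns=[f"{f}_{p}" for f, p in desc.columns],
    ).to_csv(out / "descriptors.tsv", sep="\t")
    (out / "descriptors.json").write_text(
        json.dumps(
            {
                "grid": desc.grid.to_dict(),
                "columns": [[f, p] for f, p in desc.columns],
                "config": dataclasses.asdict(desc.config),
            },
            indent=2,
        )
    )

    model = result.model
    (out / "model.json").write_text(
        json.dumps(
            {
                "n_components": model.n_components,
                "x_mean": model.x_mean.tolist(),
                "y_mean": model.y_mean,
                "coefficients": model.coefficients.tolist(),
                "grid": desc.grid.to_dict(),
                "columns": [[f, p] for f, p in desc.columns],
            }
        )
    )
    report_frame(result.report).to_csv(out / "report.tsv", sep="\t", index=False)
    (out / "report_stats.json").write_text(json.dumps(report_stats(result.report), indent=2))

    for cs in result.contour_sets:
        contours.export_contours(cs, desc.grid, out / cs.field_type, fmt="cube")
    contours.save_summary(result.contour_sets, desc.grid, out / "contour_summary.json")

    artifact_names = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    from importlib.metadata import version as pkg_version

    def _safe_version(name: str) -> str:
        try:
            return pkg_version(name)
        except Exception:
            return "unknown"

    manifest = {
        "config": result.config.to_dict(),
        "seed": result.config.seed,
        "versions": {
            "python": sys.version.split()[0],
            **{n: _safe_version(n) for n in ("triazqsar", "numpy", "scipy", "pandas", "scikit-learn", "rdkit")},
        },
        "artifacts": {name: _sha256(out / name) for name in artifact_names},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
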