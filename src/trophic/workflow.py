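"""I/O, validation, and the end-to-end pipeline.

Tables travel as flat TSV/CSV with explicit headers: the read table (rows =
OTUs, first columns ``otu_id`` and ``taxogroup``, then one integer column per
sample), a per-sample totals table, a sample-metadata table keyed by
``sample_id``, a trait CSV and (optionally) a long-format growth-counts CSV.
``run_pipeline`` chains the stages traits -> niches -> ordination -> model
and records a manifest with input checksums, seeds, versions and runtimes so
a rerun with the same configuration is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from trophic import growthfit, nichemodel, ordination, tradecomp, tradeoff

__all__ = ["PipelineConfig", "load_tables", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, toggles and seeds for one pipeline run."""

    reads_path: str
    totals_path: str
    metadata_path: str
    traits_path: str
    out_dir: str
    counts_path: str | None = None
    seed: int = 0
    run_growth: bool = False
    run_tradeoff: bool = True
    run_depth_glmm: bool = True
    run_chla_glmm: bool = True
    run_pcoa: bool = True
    run_competition: bool = True
    subset: str = "all"
    glmm_fit_method: str = "map_laplace"
    n_boot: int = 1000
    competition_grid_size: int = 5
    n_strategies: int = 21
    phi: float | None = None  # None: use the tradeoff stage's estimate

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _read_reads_table(reads_path, totals_path) -> nichemodel.ReadCountTable:
    frame = pd.read_csv(reads_path, sep="\t")
    for col in ("otu_id", "taxogroup"):
        if col not in frame.columns:
            raise ValueError(f"{reads_path}: missing required column {col!r}")
    if frame["otu_id"].duplicated().any():
        dups = frame.loc[frame["otu_id"].duplicated(), "otu_id"].tolist()
        raise ValueError(f"{reads_path}: duplicate OTU ids {dups}")
    sample_cols = [c for c in frame.columns if c not in ("otu_id", "taxogroup")]
    reads = np.empty((len(frame), len(sample_cols)), dtype=np.int64)
    for jx, col in enumerate(sample_cols):
        vals = frame[col]
        as_float = vals.astype(float)
        if not np.all(as_float == np.floor(as_float)):
            bad = int(np.argmax(as_float != np.floor(as_float)))
            raise ValueError(
                f"{reads_path}: non-integer read count {vals.iloc[bad]!r} "
                f"(otu {frame['otu_id'].iloc[bad]!r}, sample {col!r})"
            )
        reads[:, jx] = as_float.astype(np.int64)
    totals_frame = pd.read_csv(totals_path, sep="\t")
    for col in ("sample_id", "total_reads"):
        if col not in totals_frame.columns:
            raise ValueError(f"{totals_path}: missing required column {col!r}")
    totals_map = dict(zip(totals_frame["sample_id"], totals_frame["total_reads"]))
    missing = [s for s in sample_cols if s not in totals_map]
    if missing:
        raise ValueError(f"{totals_path}: no totals for samples {missing}")
    totals = np.array([int(totals_map[s]) for s in sample_cols])
    return nichemodel.ReadCountTable(
        otu_ids=list(frame["otu_id"]),
        sample_ids=sample_cols,
        reads=reads,
        totals=totals,
        taxon_of_otu=dict(zip(frame["otu_id"], frame["taxogroup"])),
    )


def load_tables(config: PipelineConfig):
    """Load and cross-validate all pipeline inputs.

    Returns ``(table, meta, traits, series)`` where ``series`` is a (possibly
    empty) list of growth-count series.  Violations raise with row/column
    context: trait OTUs absent from the read table, metadata missing a sample
    present in the reads, duplicate ids, and non-integer read cells.
    """
    table = _read_reads_table(config.reads_path, config.totals_path)
    meta = pd.read_csv(config.metadata_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ValueError(f"{config.metadata_path}: missing required column 'sample_id'")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{config.metadata_path}: duplicate sample ids")
    missing_meta = set(table.sample_ids) - set(meta["sample_id"])
    if missing_meta:
        raise ValueError(
            f"{config.metadata_path}: metadata missing samples present in reads: "
            f"{sorted(missing_meta)}"
        )
    traits = tradeoff.frame_to_records(pd.read_csv(config.traits_path))
    known_otus = set(table.otu_ids)
    orphans = [t.otu_id for t in traits if t.otu_id is not None and t.otu_id not in known_otus]
    if orphans:
        raise ValueError(f"{config.traits_path}: trait OTUs absent from read table: {orphans}")
    series = growthfit.read_counts_csv(config.counts_path) if config.counts_path else []
    return table, meta, traits, series


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the configured stages and write outputs plus a manifest.

    Stage order mirrors the analysis chain: growth fits -> tradeoff ->
    niche GLMMs -> ordination -> competition model.  Any stage failure aborts
    with the stage name; completed outputs are preserved on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, meta, traits, series = load_tables(config)
    manifest: dict[str, Any] = {
        "config": asdict(config),
        "inputs": {
            name: _sha256(p)
            for name, p in {
                "reads": config.reads_path,
                "totals": config.totals_path,
                "metadata": config.metadata_path,
                "traits": config.traits_path,
                **({"counts": config.counts_path} if config.counts_path else {}),
            }.items()
        },
        "seed": config.seed,
        "versions": {"trophic": _package_version(), "numpy": np.__version__},
        "stages": {},
    }

    phi_estimate = config.phi

    def _stage(name, enabled, fn):
        nonlocal manifest
        if not enabled:
            return
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "status": "complete",
            "runtime_s": round(time.perf_counter() - t0, 3),
            "outputs": [str(p) for p in outputs],
        }

    def growth_stage():
        fits = [growthfit.fit_growth_model(growthfit.trim_decline_phase(s)) for s in series]
        path = out / "growth_fits.csv"
        growthfit.fits_to_frame(fits).to_csv(path, index=False)
        return [path]

    def tradeoff_stage():
        nonlocal phi_estimate
        rho_mix, p_mix = tradeoff.correlate_traits(traits, "mixotrophs_only")
        rho_all, p_all = tradeoff.correlate_traits(traits, "all")
        fit = tradeoff.estimate_phi(traits, n_boot=config.n_boot, seed=config.seed)
        if config.phi is None:
            phi_estimate = fit.phi
        path = out / "tradeoff_fit.json"
        path.write_text(json.dumps({
            "phi": fit.phi, "ci_low": fit.ci_low, "ci_high": fit.ci_high,
            "n_strains": fit.n_strains, "n_boot": fit.n_boot,
            "n_boot_skipped": fit.n_boot_skipped,
            "spearman_mixotrophs": {"rho": rho_mix, "p": p_mix},
            "spearman_all": {"rho": rho_all, "p": p_all},
        }, indent=2))
        return [path]

    def glmm_stage(env_kind):
        def _run():
            fit = nichemodel.fit_trait_niche_glmm(
                table, meta, traits, env_kind=env_kind, subset=config.subset,
                fit_method=config.glmm_fit_method, seed=config.seed,
            )
            summaries = nichemodel.derive_otu_niche_summaries(fit, traits)
            base = out / f"glmm_{env_kind}"
            csv_path = base.with_suffix(".csv")
            summaries.to_csv(csv_path, index=False)
            json_path = base.with_suffix(".json")
            json_path.write_text(json.dumps({
                "creff": fit.creff, "creff_low": fit.creff_low,
                "creff_high": fit.creff_high, "env_kind": env_kind,
                "fit_method": fit.fit_method,
                "r_squared": summaries.attrs["r_squared"],
                "diagnostics": fit.diagnostics,
            }, indent=2, default=str))
            return [csv_path, json_path]
        return _run

    def pcoa_stage():
        surface = meta.loc[meta["layer"] == "surface", "sample_id"].tolist()
        res = ordination.pcoa_composition(table, samples=surface)
        env_corr = ordination.correlate_axis_environment(res, meta)
        r, p = ordination.correlate_axis_trait(res, traits)
        scores_path = out / "pcoa_scores.csv"
        res.axis_scores.to_csv(scores_path)
        corr_path = out / "pcoa_correlations.csv"
        env_corr.to_csv(corr_path, index=False)
        summary_path = out / "pcoa_summary.json"
        summary_path.write_text(json.dumps({
            "variance_explained": res.variance_explained[:5].tolist(),
            "trait_axis_r": r, "trait_axis_p": p,
        }, indent=2))
        return [scores_path, corr_path, summary_path]

    def competition_stage():
        phi = phi_estimate if phi_estimate is not None else 1.8
        params = tradecomp.CompetitionParams(phi=phi, n_strategies=config.n_strategies)
        k = config.competition_grid_size
        grid = tradecomp.sweep_environment_grid(
            params,
            N_in_grid=np.geomspace(0.25, 10.0, k),
            irradiance_grid=np.geomspace(10.0, 200.0, k),
        )
        path = out / "competition_grid.csv"
        grid.to_csv(path, index=False)
        return [path]

    _stage("growth", config.run_growth and bool(series), growth_stage)
    _stage("tradeoff", config.run_tradeoff, tradeoff_stage)
    _stage("glmm_depth", config.run_depth_glmm, glmm_stage("depth_binary"))
    _stage("glmm_chla", config.run_chla_glmm, glmm_stage("chla_continuous"))
    _stage("pcoa", config.run_pcoa, pcoa_stage)
    _stage("competition", config.run_competition, competition_stage)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _package_version() -> str:
    from trophic import __version__

    return __version__
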