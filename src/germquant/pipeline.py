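"""End-to-end orchestration: manifest in, per-sample and per-group results out.

A run is driven by a :class:`RunConfig` (every tunable of the analysis,
with defaults matching the standard protocol: anterior fraction 0.15,
300-point profiles, 10,000 bootstrap iterations, alpha 0.05) and a
manifest CSV whose rows point at image + mask files with orientation
metadata.  Per-row failures are collected and reported, not fatal, so one
corrupt file does not abort a cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .colocal import ColocSettings, colocalization
from .enrichment import (
    aggregate_profiles,
    anterior_integrated_enrichment,
    ap_profile,
    zscore_field,
)
from .polestats import (
    bootstrap_diff_means,
    compare_penetrance,
    summarize_scores,
    validate_score_table,
)
from .prep import OrientedSample, anterior_region, orient_sample, sum_project
from .simulate import ImageSimParams, generate_sample_image, write_micrograph

logger = logging.getLogger("germquant")

MANIFEST_COLUMNS = (
    "sample_id",
    "genotype",
    "stage",
    "image_path",
    "mask_path",
    "rotation_deg",
    "flip_lr",
)


@dataclass
class RunConfig:
    """All tunables of one pipeline run.

    Defaults follow the standard protocol: anterior-most 15% of mask
    pixels, 300-point AP profiles, mean+2SD anchor threshold with a 1 px
    Gaussian filter, 10,000 bootstrap iterations, alpha = 0.05.
    """

    anterior_fraction: float = 0.15
    anterior_mode: str = "pixels"
    n_profile_points: int = 300
    threshold_mode: str = "mean_plus_2sd"
    top_fraction: float = 0.175
    gaussian_sigma: float = 1.0
    min_pixels: int = 2
    bootstrap_iters: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    anchor_channel: str = "HA"
    target_channels: tuple[str, ...] = ("target",)
    channel_names: tuple[str, ...] = ("HA", "target")
    control_genotype: str = ""
    fisher_direction: str = "less"

    @property
    def coloc_settings(self) -> ColocSettings:
        return ColocSettings(
            threshold_mode=self.threshold_mode,
            top_fraction=self.top_fraction,
            gaussian_sigma=self.gaussian_sigma,
            min_pixels=self.min_pixels,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON; unknown keys are rejected."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("target_channels", "channel_names"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_sample(row: pd.Series, channel_names: tuple[str, ...]) -> OrientedSample:
    """Read one manifest row into an oriented sample.

    The image TIFF may be ``(channel, y, x)`` or a ``(z, channel, y, x)``
    stack (sum-projected first); the mask TIFF/PNG is any nonzero-is-inside
    2-D image.
    """
    import tifffile

    from .prep import MicrographStack

    img = np.asarray(tifffile.imread(row["image_path"]))
    if img.ndim == 2:
        img = img[None]
    if img.ndim == 4:
        img = sum_project(MicrographStack(voxels=img, channel_names=channel_names))
    if img.ndim != 3:
        raise ValueError(f"image must be 2-D, 3-D or 4-D, got ndim={img.ndim}")
    mask = np.asarray(tifffile.imread(row["mask_path"])) > 0
    return orient_sample(
        img,
        mask,
        rotation_deg=float(row.get("rotation_deg", 0.0)),
        flip_lr=str(row.get("flip_lr", False)).lower() in ("1", "true", "yes"),
        channel_names=channel_names,
        sample_id=str(row["sample_id"]),
    )


def analyse_sample(sample: OrientedSample, config: RunConfig) -> dict:
    """Run the full per-sample quantification.

    Returns enrichment rows (one per target channel), AP profiles for the
    anchor and targets, and anchor-vs-target colocalization rows.
    """
    region = anterior_region(sample, config.anterior_fraction, config.anterior_mode)
    enrich_rows, coloc_rows, profiles = [], [], {}
    for ch in (config.anchor_channel, *config.target_channels):
        zf = zscore_field(sample, ch)
        profiles[ch] = ap_profile(zf, sample, n_points=config.n_profile_points)
        res = anterior_integrated_enrichment(
            zf, region, fraction=config.anterior_fraction,
            mode=config.anterior_mode, sample_id=sample.sample_id,
        )
        enrich_rows.append(
            {
                "sample_id": sample.sample_id,
                "channel": ch,
                "enrichment_value": res.value,
                "n_pixels": res.n_pixels,
                "fraction": res.fraction,
                "mode": res.mode,
            }
        )
    for ch in config.target_channels:
        c = colocalization(
            sample, config.anchor_channel, ch, region, config.coloc_settings
        )
        coloc_rows.append(
            {
                "sample_id": sample.sample_id,
                "pair": f"{c.channel_pair[0]}-{c.channel_pair[1]}",
                "mode": config.threshold_mode,
                "sigma": config.gaussian_sigma,
                "n_pixels": c.n_pixels,
                "r": c.r,
                "defined": c.defined,
            }
        )
    return {"enrichment": enrich_rows, "coloc": coloc_rows, "profiles": profiles}


def run_enrichment_pipeline(
    config: RunConfig, manifest: pd.DataFrame | str | Path, out_dir: str | Path
) -> dict:
    """Quantify every manifest sample and aggregate per genotype.

    Writes ``enrichment.csv``, ``coloc.csv``, ``profiles.csv`` (per-group
    mean and 95% CI along the normalized AP axis), ``comparisons.json``
    (bootstrap tests of each genotype's enrichment vs the control group,
    when a control is configured) and ``run_log.json``.  Returns a dict
    with the output paths, row counts, and any per-row errors.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    missing = set(("sample_id", "genotype", "image_path", "mask_path")) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    enrich_rows, coloc_rows, errors = [], [], []
    group_profiles: dict[tuple[str, str], list] = {}
    for _, row in manifest.iterrows():
        try:
            sample = load_sample(row, config.channel_names)
            res = analyse_sample(sample, config)
        except Exception as exc:  # noqa: BLE001 — per-row isolation is the contract
            errors.append({"sample_id": str(row.get("sample_id")), "error": str(exc)})
            logger.error("sample %s failed: %s", row.get("sample_id"), exc)
            continue
        genotype = str(row["genotype"])
        for r in res["enrichment"]:
            enrich_rows.append({**r, "genotype": genotype})
        for r in res["coloc"]:
            coloc_rows.append({**r, "genotype": genotype})
        for ch, prof in res["profiles"].items():
            group_profiles.setdefault((genotype, ch), []).append(prof)

    enrich_df = pd.DataFrame(
        enrich_rows,
        columns=["sample_id", "genotype", "channel", "enrichment_value",
                 "n_pixels", "fraction", "mode"],
    )
    coloc_df = pd.DataFrame(
        coloc_rows,
        columns=["sample_id", "genotype", "pair", "mode", "sigma",
                 "n_pixels", "r", "defined"],
    )
    profile_rows = []
    for (genotype, ch), profs in sorted(group_profiles.items()):
        ens = aggregate_profiles(profs)
        for i in range(len(ens.positions)):
            profile_rows.append(
                {
                    "genotype": genotype,
                    "channel": ch,
                    "position": ens.positions[i],
                    "mean": ens.mean[i],
                    "ci_low": ens.ci_low[i],
                    "ci_high": ens.ci_high[i],
                    "n": ens.n_samples,
                }
            )
    profile_df = pd.DataFrame(
        profile_rows,
        columns=["genotype", "channel", "position", "mean", "ci_low", "ci_high", "n"],
    )

    comparisons = []
    if config.control_genotype and not enrich_df.empty:
        ctrl = enrich_df[enrich_df["genotype"] == config.control_genotype]
        if ctrl.empty:
            raise ValueError(
                f"control genotype {config.control_genotype!r} absent from manifest"
            )
        for genotype in sorted(set(enrich_df["genotype"]) - {config.control_genotype}):
            for ch in (config.anchor_channel, *config.target_channels):
                x = enrich_df.query("genotype == @genotype and channel == @ch")[
                    "enrichment_value"
                ].to_numpy()
                y = ctrl[ctrl["channel"] == ch]["enrichment_value"].to_numpy()
                if x.size == 0 or y.size == 0:
                    continue
                bt = bootstrap_diff_means(
                    x, y, n_iterations=config.bootstrap_iters, seed=config.seed
                )
                comparisons.append(
                    {
                        "genotype": genotype,
                        "control": config.control_genotype,
                        "channel": ch,
                        "observed_diff": bt.observed_diff,
                        "p_value": bt.p_value,
                        "n_iterations": bt.n_iterations,
                        "seed": bt.seed,
                        "sidedness": bt.sidedness,
                        "significant": bt.p_value < config.alpha,
                    }
                )

    paths = {
        "enrichment": out_dir / "enrichment.csv",
        "coloc": out_dir / "coloc.csv",
        "profiles": out_dir / "profiles.csv",
        "comparisons": out_dir / "comparisons.json",
        "run_log": out_dir / "run_log.json",
    }
    enrich_df.to_csv(paths["enrichment"], index=False)
    coloc_df.to_csv(paths["coloc"], index=False)
    profile_df.to_csv(paths["profiles"], index=False)
    paths["comparisons"].write_text(json.dumps(comparisons, indent=2, sort_keys=True))
    paths["run_log"].write_text(
        json.dumps(
            {
                "version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "n_samples": int(len(manifest)),
                "n_failed": len(errors),
                "errors": errors,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "n_samples": int(len(manifest)) - len(errors),
        "errors": errors,
    }


def run_polestats(
    config: RunConfig, score_table: pd.DataFrame | str | Path, out_dir: str | Path
) -> dict:
    """Summarize a score table per genotype and test each vs the control.

    Writes ``summaries.csv`` and, when a control genotype is configured,
    ``tests.json`` with one-sided Fisher penetrance comparisons and pooled
    bootstrap tests on the anterior pole-cell counts of positive embryos.
    """
    if not isinstance(score_table, pd.DataFrame):
        score_table = pd.read_csv(score_table)
    validate_score_table(score_table)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genotypes = sorted(score_table["genotype"].unique())
    summaries = {g: summarize_scores(score_table, g) for g in genotypes}
    summary_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries.values()])
    summary_df.to_csv(out_dir / "summaries.csv", index=False)

    tests = []
    if config.control_genotype:
        if config.control_genotype not in summaries:
            raise ValueError(
                f"control genotype {config.control_genotype!r} absent from table"
            )
        ctrl = summaries[config.control_genotype]
        ctrl_counts = score_table.query(
            "genotype == @config.control_genotype and category == 'anterior_pole_cells'"
        )["n_anterior"].to_numpy()
        for g in genotypes:
            if g == config.control_genotype:
                continue
            fisher = compare_penetrance(
                summaries[g], ctrl, direction=config.fisher_direction, alpha=config.alpha
            )
            entry = {"genotype": g, "fisher": fisher}
            var_counts = score_table.query(
                "genotype == @g and category == 'anterior_pole_cells'"
            )["n_anterior"].to_numpy()
            if var_counts.size and ctrl_counts.size:
                bt = bootstrap_diff_means(
                    var_counts,
                    ctrl_counts,
                    n_iterations=config.bootstrap_iters,
                    seed=config.seed,
                )
                entry["count_bootstrap"] = {
                    "observed_diff": bt.observed_diff,
                    "p_value": bt.p_value,
                    "n_iterations": bt.n_iterations,
                    "significant": bt.p_value < config.alpha,
                }
            tests.append(entry)
        (out_dir / "tests.json").write_text(json.dumps(tests, indent=2, sort_keys=True))

    return {"summaries": summaries, "tests": tests, "out_dir": str(out_dir)}


def simulate_cohort(
    out_dir: str | Path,
    genotypes: dict[str, float],
    n_per_genotype: int = 10,
    seed: int = 0,
    **param_overrides,
) -> pd.DataFrame:
    """Write a synthetic cohort to disk and return its manifest.

    ``genotypes`` maps genotype name to anterior signal amplitude, so a
    "wild-type" and an amplitude-0 "negative control" cohort can be
    generated in one call.  Seeds are derived deterministically from
    ``seed`` and the sample index.
    """
    out_dir = Path(out_dir)
    rows = []
    idx = 0
    for genotype in sorted(genotypes):
        amplitude = genotypes[genotype]
        for i in range(n_per_genotype):
            params = ImageSimParams(
                amplitude=amplitude, seed=seed * 100_000 + idx, **param_overrides
            )
            sid = f"{genotype}_{i:03d}"
            mic = generate_sample_image(params, sample_id=sid)
            row = write_micrograph(mic, out_dir / "images", sid)
            rows.append({**row, "genotype": genotype, "stage": "sim"})
            idx += 1
    manifest = pd.DataFrame(rows)[
        ["sample_id", "genotype", "stage", "image_path", "mask_path",
         "rotation_deg", "flip_lr"]
    ]
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
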