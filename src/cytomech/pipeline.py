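"""Reproducible simulate → fit → report orchestration.

A single config drives all stages.  ``run_simulate`` writes every
synthetic dataset with its ground-truth tables and a manifest (config
hash, seed, version, file hashes); ``run_fit`` runs the osmotic, Hertz and
morphometry analyses over those datasets; ``run_report`` assembles
group-level summary tables, hypothesis tests, and the cross-scale scaling
regression.  Reruns with an identical manifest reproduce identical
numbers.
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
import tifffile

from . import __version__
from . import io as cio
from .hertz import fit_hertz
from .morphometry import (
    GateConfig,
    circularity,
    gate_single_cells,
    nuclear_similarity,
    segment_cells,
    shape_metrics,
)
from .osmotic import (
    ModelConstants,
    OsmoticProtocol,
    OsmoticStep,
    fit_two_step_sequence,
)
from .stats import compare_groups, scaling_relationship, summarize_groups
from .synthetic import (
    GROUP_PRESETS,
    NoiseModel,
    make_channel_pair,
    make_force_curves,
    make_shape_masks,
    make_volume_traces,
    render_frame_sequence,
    sample_population,
)

logger = logging.getLogger("cytomech")

__all__ = ["RunConfig", "run_simulate", "run_fit", "run_report"]

NULL_CELL = "null (no reported value)"


@dataclass
class RunConfig:
    """Configuration for a full simulate/fit/report run."""

    seed: int = 0
    groups: list[str] = field(
        default_factory=lambda: ["untreated", "TNFa"]
    )
    control_group: str = "untreated"
    n_osmotic: int = 12
    n_radius: int = 200
    n_modulus: int = 50
    n_shapes: int = 20
    protocol_steps: list[tuple[float, float]] = field(
        default_factory=lambda: [(466.0, 300.0), (333.0, 300.0)]
    )
    equilibration_osmolarity: float = 333.0
    temperature: float = 295.15
    pixel_size: float = 0.2
    sampling_interval: float = 2.0
    radius_cv: float = 0.05
    force_sd_frac: float = 0.05
    image_noise_sd: float = 5.0
    channel_rho: float = 0.5
    tip_radius: float = 3e-6
    gate_min_area: float = 50.0
    gate_max_area: float = 700.0
    gate_max_aspect: float = 2.0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = cio.load_config_file(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for g in cfg.groups:
            if g not in GROUP_PRESETS:
                raise ValueError(
                    f"unknown group preset '{g}'; available: {sorted(GROUP_PRESETS)}"
                )
        return cfg

    @property
    def protocol(self) -> OsmoticProtocol:
        return OsmoticProtocol(
            steps=tuple(OsmoticStep(c, d) for c, d in self.protocol_steps),
            equilibration_osmolarity=self.equilibration_osmolarity,
        )

    @property
    def constants(self) -> ModelConstants:
        return ModelConstants(temperature=self.temperature)

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(
            radius_cv=self.radius_cv,
            force_sd_frac=self.force_sd_frac,
            image_noise_sd=self.image_noise_sd,
        )

    @property
    def gate(self) -> GateConfig:
        return GateConfig(
            min_area=self.gate_min_area,
            max_area=self.gate_max_area,
            max_aspect_ratio=self.gate_max_aspect,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def group_seed(self, group: str, assay: str) -> int:
        """Stable per-(group, assay) sub-seed below 2**31."""
        h = hashlib.sha256(f"{self.seed}:{group}:{assay}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(config: RunConfig, outdir: Path, files: list[Path]) -> None:
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "files": {str(p.relative_to(outdir)): _file_hash(p) for p in sorted(files)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_simulate(config: RunConfig, outdir: str | Path) -> Path:
    """Generate every synthetic dataset plus ground truth and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    protocol = config.protocol

    for group in config.groups:
        preset = GROUP_PRESETS[group]
        gdir = outdir / group
        gdir.mkdir(exist_ok=True)

        # 1. population truths (osmotic cohort)
        pop = sample_population(preset, config.n_osmotic, config.group_seed(group, "pop"))
        pop_path = gdir / "population.csv"
        pop.to_csv(pop_path, index=False)
        files.append(pop_path)

        # 2. volume traces
        traces = make_volume_traces(
            pop, protocol, config.noise, config.group_seed(group, "traces"),
            config.constants, config.sampling_interval,
        )
        tr_path = gdir / "volume_traces.csv"
        cio.write_traces_csv(traces, tr_path)
        files.append(tr_path)

        # 3. radius field (one frame, n_radius disks)
        rng = np.random.default_rng(config.group_seed(group, "radius"))
        if preset.radius is not None and preset.radius[1] is not None:
            rad_mean, rad_sd = preset.radius
            radii = np.clip(rng.normal(rad_mean, rad_sd, config.n_radius), 1.0, None)
            stack, truth = render_frame_sequence(
                radii.reshape(1, -1), config.pixel_size,
                noise=config.noise, seed=config.group_seed(group, "render"),
            )
            img_path = gdir / "radius_field.tif"
            cio.write_stack(stack, img_path)
            truth_path = gdir / "radius_truth.csv"
            truth.to_csv(truth_path, index=False)
            files += [img_path, truth_path]

        # 4. force curves
        rng = np.random.default_rng(config.group_seed(group, "afm"))
        mod_mean, mod_sd = preset.require("modulus")
        moduli = np.clip(
            rng.normal(mod_mean, mod_sd, config.n_modulus), 0.05, None
        ) * 1e3  # kPa -> Pa
        offsets = rng.uniform(5e-8, 2e-7, config.n_modulus)
        curves = make_force_curves(
            moduli, config.tip_radius, contact_offsets=offsets,
            noise=config.noise, seed=config.group_seed(group, "afm_noise"),
        )
        fc_path = gdir / "force_curves.csv"
        cio.write_force_curves_csv(curves, fc_path)
        ft_path = gdir / "force_truth.csv"
        pd.DataFrame(
            {"cell_id": [c.cell_id for c in curves], "modulus_Pa": moduli,
             "contact_m": offsets}
        ).to_csv(ft_path, index=False)
        files += [fc_path, ft_path]

        # 5. shape masks (protrusion amplitude emulating the group phenotype)
        if preset.circularity_rel is not None:
            amp = float(np.clip(0.8 * (1.0 - preset.circularity_rel), 0.0, 0.9))
            masks, shape_truth = make_shape_masks(
                config.n_shapes, amp, seed=config.group_seed(group, "shapes")
            )
            side = max(m.shape[0] for m in masks)
            padded = np.zeros((len(masks), side, side), dtype=np.uint8)
            for i, m in enumerate(masks):
                padded[i, : m.shape[0], : m.shape[1]] = m
            mask_path = gdir / "shape_masks.tif"
            tifffile.imwrite(mask_path, padded, photometric="minisblack")
            st_path = gdir / "shape_truth.csv"
            shape_truth.to_csv(st_path, index=False)
            files += [mask_path, st_path]

        # 6. colocalization channel pair
        a, b, mask = make_channel_pair(
            config.channel_rho, seed=config.group_seed(group, "channels")
        )
        ch_path = gdir / "channels.tif"
        tifffile.imwrite(
            ch_path,
            np.stack([a, b, mask.astype(float)]).astype(np.float32),
            photometric="minisblack",
        )
        files.append(ch_path)

    _write_manifest(config, outdir, files)
    logger.info("simulate: wrote %d files to %s", len(files), outdir)
    return outdir / "manifest.json"


def _fit_osmotic(config: RunConfig, gdir: Path, group: str) -> pd.DataFrame:
    tr_path = gdir / "volume_traces.csv"
    if not tr_path.exists():
        raise FileNotFoundError(f"missing dataset: {tr_path}")
    traces = cio.read_traces_csv(tr_path, config.sampling_interval)
    rows = []
    for tr in traces:
        for res in fit_two_step_sequence(tr, config.protocol, config.constants):
            rows.append(
                {
                    "group": group,
                    "cell_id": res.cell_id,
                    "step": res.step_index,
                    "step_label": res.step_label,
                    "Lp": res.lp,
                    "phir": res.phi_ir,
                    "rss": res.rss,
                    "r2": res.r_squared,
                    "converged": res.converged,
                    "qc_flags": ";".join(res.qc_flags),
                }
            )
    return pd.DataFrame(rows)


def _fit_hertz_group(config: RunConfig, gdir: Path, group: str) -> pd.DataFrame:
    fc_path = gdir / "force_curves.csv"
    if not fc_path.exists():
        raise FileNotFoundError(f"missing dataset: {fc_path}")
    rows = []
    for curve in cio.read_force_curves_csv(fc_path):
        fit = fit_hertz(curve)
        rows.append(
            {
                "group": group,
                "cell_id": curve.cell_id,
                "E_Pa": fit.modulus,
                "nu": fit.poisson_ratio,
                "contact_m": fit.contact_offset,
                "baseline_N": fit.baseline,
                "rss": fit.rss,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def _fit_morphometry(config: RunConfig, gdir: Path, group: str) -> pd.DataFrame:
    img_path = gdir / "radius_field.tif"
    if not img_path.exists():
        return pd.DataFrame()
    stack = cio.read_stack(img_path)
    frames = []
    for fi, frame in enumerate(stack):
        lm = segment_cells(frame, pixel_size=config.pixel_size, frame_index=fi)
        df = shape_metrics(lm)
        df.insert(0, "group", group)
        frames.append(df)
    metrics = pd.concat(frames, ignore_index=True)
    gated, removed = gate_single_cells(metrics, config.gate)
    logger.info("%s morphometry: %d objects, removed %s", group, len(metrics), removed)
    return gated


def _fit_shapes(config: RunConfig, gdir: Path, group: str) -> pd.DataFrame:
    mask_path = gdir / "shape_masks.tif"
    if not mask_path.exists():
        return pd.DataFrame()
    masks = tifffile.imread(mask_path)
    if masks.ndim == 2:
        masks = masks[None]
    rows = [
        {"group": group, "mask": i, "circularity": circularity(m > 0)}
        for i, m in enumerate(masks)
    ]
    return pd.DataFrame(rows)


def _score_channels(config: RunConfig, gdir: Path, group: str) -> dict | None:
    ch_path = gdir / "channels.tif"
    if not ch_path.exists():
        return None
    a, b, mask = tifffile.imread(ch_path)
    score, valid = nuclear_similarity(a, b, mask > 0.5)
    return {"group": group, "similarity": score, "valid": valid}


def run_fit(config: RunConfig, indir: str | Path, outdir: str | Path) -> Path:
    """Run every analysis stage over simulated (or real) datasets."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    osmotic, hertz, morpho, shapes, chans = [], [], [], [], []
    for group in config.groups:
        gdir = indir / group
        if not gdir.exists():
            raise FileNotFoundError(f"missing dataset directory: {gdir}")
        osmotic.append(_fit_osmotic(config, gdir, group))
        hertz.append(_fit_hertz_group(config, gdir, group))
        morpho.append(_fit_morphometry(config, gdir, group))
        shapes.append(_fit_shapes(config, gdir, group))
        ch = _score_channels(config, gdir, group)
        if ch:
            chans.append(ch)

    pd.concat(osmotic, ignore_index=True).to_csv(outdir / "osmotic_fits.csv", index=False)
    pd.concat(hertz, ignore_index=True).to_csv(outdir / "hertz_fits.csv", index=False)
    pd.concat(morpho, ignore_index=True).to_csv(outdir / "morphometry.csv", index=False)
    pd.concat(shapes, ignore_index=True).to_csv(outdir / "shape_circularity.csv", index=False)
    pd.DataFrame(chans).to_csv(outdir / "similarity.csv", index=False)
    _write_manifest(config, outdir, list(outdir.glob("*.csv")))
    return outdir


def _tidy_results(outdir: Path) -> pd.DataFrame:
    """Stack fit outputs into a tidy (group, cell_id, metric, value) table."""
    rows = []
    osmotic = pd.read_csv(outdir / "osmotic_fits.csv")
    for _, r in osmotic.iterrows():
        flags = str(r.get("qc_flags", "") or "")
        if pd.notna(r.get("Lp")) and "lp_at_bound" not in flags:
            rows.append((r["group"], r["cell_id"], f"Lp_{r['step_label']}", r["Lp"]))
    hertz = pd.read_csv(outdir / "hertz_fits.csv")
    for _, r in hertz.iterrows():
        if pd.notna(r.get("E_Pa")) and r.get("converged", False):
            rows.append((r["group"], r["cell_id"], "modulus_kPa", r["E_Pa"] / 1e3))
    morpho = pd.read_csv(outdir / "morphometry.csv")
    if len(morpho):
        for _, r in morpho.iterrows():
            rows.append((r["group"], f"obj{int(r['label'])}", "radius_um", r["equivalent_radius_um"]))
    shapes = pd.read_csv(outdir / "shape_circularity.csv")
    if len(shapes):
        for _, r in shapes.iterrows():
            rows.append((r["group"], f"mask{int(r['mask'])}", "circularity", r["circularity"]))
    return pd.DataFrame(rows, columns=["group", "cell_id", "metric", "value"])


def run_report(config: RunConfig, resultsdir: str | Path, out: str | Path) -> Path:
    """Summaries, tests and the scaling regression, as CSV + markdown."""
    resultsdir = Path(resultsdir)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    tidy = _tidy_results(resultsdir)
    summaries = summarize_groups(tidy, control_group=config.control_group)
    summary_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])

    # quantities without a reported generating value appear as explicit nulls
    null_rows = []
    for group in config.groups:
        preset = GROUP_PRESETS[group]
        for metric, val in (
            ("circularity_rel", preset.circularity_rel),
            ("pmlc_rel", preset.pmlc_rel),
            ("lp_hypo", preset.lp_hypo),
        ):
            if val is None:
                null_rows.append(
                    {"group": group, "metric": metric, "n": 0,
                     "mean": NULL_CELL, "sd": NULL_CELL,
                     "control_normalized_mean": NULL_CELL}
                )
    if null_rows:
        summary_df = pd.concat([summary_df, pd.DataFrame(null_rows)], ignore_index=True)
    summary_df.to_csv(out / "group_summaries.csv", index=False)

    test_rows = []
    for metric, sub in tidy.groupby("metric", sort=False):
        counts = sub.groupby("group")["value"].count()
        usable = counts[counts >= 2].index
        sub = sub[sub["group"].isin(usable)]
        if sub["group"].nunique() < 2:
            continue
        res = compare_groups(sub[["group", "value"]])
        if res["design"] == "two-group":
            test_rows.append({"metric": metric, "test": "t", "stat": res["t"], "p": res["p"]})
        else:
            test_rows.append({"metric": metric, "test": "anova", "stat": res["F"], "p": res["p"]})
            for _, r in res["lsd"].iterrows():
                test_rows.append(
                    {"metric": metric, "test": f"LSD {r['group_a']} vs {r['group_b']}",
                     "stat": r["t"], "p": r["p"]}
                )
    tests_df = pd.DataFrame(test_rows)
    tests_df.to_csv(out / "tests.csv", index=False)

    # cross-scale scaling: circularity group means vs hyper-osmotic Lp means
    scaling_lines = []
    means = (
        tidy.groupby(["group", "metric"])["value"].mean().unstack()
        if len(tidy)
        else pd.DataFrame()
    )
    if {"circularity", "Lp_hyper"}.issubset(means.columns):
        pts = means[["circularity", "Lp_hyper"]].dropna()
        if len(pts) >= 3:
            reg = scaling_relationship(
                pts["circularity"].to_numpy(), pts["Lp_hyper"].to_numpy()
            )
            scaling_lines.append(
                f"circularity vs hyper-osmotic Lp: slope={reg.slope:.3e}, "
                f"R2={reg.r_squared:.3f}, p={reg.p_value:.3g}, n={reg.n_points}"
            )

    report = ["# cytomech run report", "", f"seed: {config.seed}",
              f"config hash: {config.config_hash()}", "", "## Group summaries", ""]
    report.append(summary_df.to_string(index=False))
    report += ["", "## Hypothesis tests", "", tests_df.to_string(index=False)]
    if scaling_lines:
        report += ["", "## Scaling regression", ""] + scaling_lines
    (out / "report.md").write_text("\n".join(report) + "\n")
    return out / "report.md"
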