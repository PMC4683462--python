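"""End-to-end analysis: read/simulate -> model -> classify -> gamut -> bootstrap.

One configuration drives the whole chain and produces a tidy report
bundle: ``summary.json`` (headline quantities, every percentage naming its
denominator), ``mechanism_table.csv`` (per-mechanism share and gamut),
``sex_table.csv`` (volumes, overlap, shared/unique loci, female/male ratio
bootstraps), ``order_table.csv`` (per-order observed vs size-matched null,
per sex and metric) and yz/yx shadow plots.

Deterministic given config + seed: all randomness derives from the root
seed, and outputs carry no timestamps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import bootstrap_sex_ratio, order_table
from .classify import ClassifierConfig, classify_set
from .gamut import (DEFAULT_CELL_SIZE, hull_overlap, hull_volume,
                    locus_summary, rasterize_loci, shared_unique_loci,
                    volume_fraction)
from .plots import shadow_plot
from .simulate import AvifaunaConfig, gen_avifauna
from .spectra import average_replicates, read_spectra, resample_set
from .visual import TETRA_VOLUME, aggregate_species_sex, build_sensitivity_set, model_set


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Configuration of one full run.

    With ``input_spectra`` unset, a synthetic avifauna is generated from
    ``avifauna`` (the study-conditions default when that is None too).
    """

    input_spectra: str | None = None
    input_format: str = "long"
    visual_system: str = "U"
    sensitivities: str | None = None
    cell_size: float = DEFAULT_CELL_SIZE
    bootstrap_B: int = 1000
    seed: int = 1
    output_dir: str = "avigamut_out"
    make_plots: bool = True
    average_within_specimen: bool = True
    avifauna: dict | None = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _stage_seed(seed: int, k: int) -> int:
    return int((seed * 1000003 + k) % 2**31)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the whole pipeline; returns the summary dict it also writes.

    Any stage failure removes files already written and raises
    :class:`StageError` naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    stage = "setup"
    try:
        stage = "acquire"
        if config.input_spectra is not None:
            sset = read_spectra(config.input_spectra, config.input_format)
            sset = resample_set(sset)
        else:
            avi_kwargs = dict(config.avifauna or {})
            avi_kwargs.setdefault("seed", config.seed)
            sset, _truth = gen_avifauna(AvifaunaConfig(**avi_kwargs))
        if config.average_within_specimen:
            sset = average_replicates(sset)

        stage = "visual_model"
        sens = build_sensitivity_set(config.visual_system,
                                     path=config.sensitivities)
        points = model_set(sset, sens)

        stage = "classify"
        labelled, shares = classify_set(sset)
        points["mechanism"] = labelled["mechanism"].to_numpy()

        stage = "aggregate"
        agg = aggregate_species_sex(points)
        mech_mode = (points.groupby(["species", "sex", "patch"], sort=False)
                     ["mechanism"]
                     .agg(lambda s: s.mode().iloc[0]))
        agg = agg.merge(mech_mode.rename("mechanism").reset_index(),
                        on=["species", "sex", "patch"])

        stage = "gamut"
        hull_all = hull_volume(agg)
        loci_all = rasterize_loci(agg, config.cell_size)
        summary_loci = locus_summary(loci_all)

        mech_rows = []
        for mech, sub in agg.groupby("mechanism", sort=True):
            h = hull_volume(sub)
            lm = rasterize_loci(sub, config.cell_size)
            mech_rows.append({
                "mechanism": mech,
                "n_patches": len(sub),
                "share_pct_of_patches": 100.0 * len(sub) / len(agg),
                "hull_volume": h.volume,
                "pct_of_tetra_volume": 100.0 * volume_fraction(h.volume),
                "n_loci": lm.n_occupied,
                "pct_of_sample_loci": 100.0 * lm.n_occupied
                                      / loci_all.n_occupied,
            })
        mech_table = pd.DataFrame(mech_rows)

        stage = "sex_comparison"
        males = agg[agg["sex"] == "male"]
        females = agg[agg["sex"] == "female"]
        hull_m, hull_f = hull_volume(males), hull_volume(females)
        overlap = hull_overlap(females, males)
        loci_m = rasterize_loci(males, config.cell_size)
        loci_f = rasterize_loci(females, config.cell_size)
        part = shared_unique_loci(loci_f, loci_m)
        ratio_loci = bootstrap_sex_ratio(
            agg, "n_loci", config.bootstrap_B,
            seed=_stage_seed(config.seed, 1), cell_size=config.cell_size)
        ratio_vol = bootstrap_sex_ratio(
            agg, "hull_volume", config.bootstrap_B,
            seed=_stage_seed(config.seed, 2), cell_size=config.cell_size)
        sex_table = pd.DataFrame([{
            "male_hull_volume": hull_m.volume,
            "female_hull_volume": hull_f.volume,
            "male_pct_of_tetra_volume": 100.0 * volume_fraction(hull_m.volume),
            "female_pct_of_tetra_volume": 100.0 * volume_fraction(hull_f.volume),
            "overlap_pct_of_female_volume": 100.0 * overlap.frac_of_a,
            "overlap_pct_of_male_volume": 100.0 * overlap.frac_of_b,
            "male_pct_of_sample_loci": 100.0 * loci_m.n_occupied
                                       / loci_all.n_occupied,
            "female_pct_of_sample_loci": 100.0 * loci_f.n_occupied
                                         / loci_all.n_occupied,
            "shared_pct_of_union_loci": 100.0 * part.frac_shared,
            "female_only_pct_of_union_loci": 100.0 * part.frac_only_a,
            "male_only_pct_of_union_loci": 100.0 * part.frac_only_b,
            "ratio_fm_loci_median": ratio_loci.median,
            "ratio_fm_loci_q025": ratio_loci.q025,
            "ratio_fm_loci_q975": ratio_loci.q975,
            "ratio_fm_volume_median": ratio_vol.median,
            "ratio_fm_volume_q025": ratio_vol.q025,
            "ratio_fm_volume_q975": ratio_vol.q975,
        }])

        stage = "order_null"
        order_frames = []
        for i, (sex, sub) in enumerate((("male", males), ("female", females))):
            for j, metric in enumerate(("hull_volume", "n_loci")):
                tab = order_table(sub, metric, config.bootstrap_B,
                                  seed=_stage_seed(config.seed, 10 + 2 * i + j),
                                  cell_size=config.cell_size)
                tab.insert(0, "sex", sex)
                tab.insert(1, "metric", metric)
                order_frames.append(tab)
        order_tab = pd.concat(order_frames, ignore_index=True)

        stage = "report"
        summary = {
            "package_version": __version__,
            "visual_system": config.visual_system,
            "cell_size": config.cell_size,
            "seed": config.seed,
            "n_spectra": len(sset),
            "n_species": int(agg["species"].nunique()),
            "n_aggregated_points": len(agg),
            "hull_volume_total": hull_all.volume,
            "pct_of_tetra_volume_total": 100.0 * volume_fraction(
                hull_all.volume),
            "tetra_volume_reference": TETRA_VOLUME,
            "n_occupied_loci_total": loci_all.n_occupied,
            "half_mass_fraction_of_loci": summary_loci.mass_fraction,
            "mechanism_shares_pct": {
                row["mechanism"]: row["share_pct_of_patches"]
                for row in mech_rows
            },
        }
        json.dump(summary, emit("summary.json").open("w"), indent=2,
                  sort_keys=True)
        mech_table.to_csv(emit("mechanism_table.csv"), index=False)
        sex_table.to_csv(emit("sex_table.csv"), index=False)
        order_tab.to_csv(emit("order_table.csv"), index=False)
        config.to_yaml(emit("config_used.yaml"))
        emit("run_log.txt").write_text(
            f"avigamut {__version__}\n"
            f"numpy {np.__version__}\npandas {pd.__version__}\n"
            f"config: {asdict(config)}\n"
            f"stages: acquire, visual_model, classify, aggregate, gamut, "
            f"sex_comparison, order_null, report\n"
        )
        if config.make_plots:
            shadow_plot(agg, "yz", config.cell_size, emit("shadow_yz.png"),
                        hue="sex")
            shadow_plot(agg, "yx", config.cell_size, emit("shadow_yx.png"),
                        hue="sex")
        return summary
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc
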