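"""End-to-end experiment: press scenarios through the dynamic ensemble and
the whole qualitative-model ladder, plus comparison tables.

For every scenario element × direction, tallies are produced for the
dynamic ensemble and for each thresholded qualitative model, reduced to
categories, and scored pairwise.  Outputs are tidy CSVs plus a JSON run
manifest recording seeds and sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjacency import (
    LADDER_LEVELS,
    SignedAdjacency,
    apply_threshold,
    build_adjacency,
    link_counts,
    to_signed_digraph,
)
from .compare import ResponseCategory, categorize_tally, model_agreement
from .dynamics import ensemble_tally
from .foodweb import FoodWeb, mass_balance
from .qnm import PressScenario, ResponseTally, simulate_press
from .synthetic import WebSpec, generate_foodweb, load_wss28

__all__ = ["ExperimentConfig", "ExperimentBundle", "run_experiment", "summarize_agreement",
           "link_count_ladder_table", "load_config"]

DYNAMIC_MODEL = "dynamic"


def model_name(level: float) -> str:
    return f"qnm{int(round(level * 100))}"


@dataclass
class ExperimentConfig:
    """Settings for one full scenario grid."""

    web: FoodWeb
    scenario_elements: tuple[str, ...]
    directions: tuple[int, ...] = (1, -1)
    ladder_levels: tuple[float, ...] = LADDER_LEVELS
    n_sims: int = 1000
    seed: int = 0
    out_dir: Path | None = None
    coupled_seeds: bool = False  # share draws across ladder levels
    run_dynamic: bool = True
    ensemble_max_draws: int = 40_000
    qnm_max_draws: int = 1_000_000
    dt: float = 1.0 / 12.0

    def __post_init__(self):
        for e in self.scenario_elements:
            self.web.index(e)  # raises KeyError with the element name
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


@dataclass
class ExperimentBundle:
    config: ExperimentConfig
    adjacency: SignedAdjacency
    tallies: dict[tuple[str, str, int], ResponseTally]  # (model, element, direction)
    categories: dict[tuple[str, str, int], dict[str, ResponseCategory]]

    @property
    def models(self) -> list[str]:
        names = [model_name(lv) for lv in self.config.ladder_levels]
        if self.config.run_dynamic:
            names = [DYNAMIC_MODEL] + names
        return names

    def tally_frame(self) -> pd.DataFrame:
        rows = []
        for (model, element, direction), tally in self.tallies.items():
            for i, e in enumerate(tally.elements):
                rows.append(
                    {
                        "model": model,
                        "scenario_element": element,
                        "direction": direction,
                        "element": e,
                        "n_pos": int(tally.positive[i]),
                        "n_neg": int(tally.negative[i]),
                        "n_neutral": int(tally.neutral[i]),
                    }
                )
        return pd.DataFrame(rows)

    def category_frame(self) -> pd.DataFrame:
        rows = []
        for (model, element, direction), cats in self.categories.items():
            for e, c in cats.items():
                rows.append(
                    {
                        "model": model,
                        "scenario_element": element,
                        "direction": direction,
                        "element": e,
                        "label": c.label,
                        "lean": c.lean,
                    }
                )
        return pd.DataFrame(rows)


def link_count_ladder_table(
    adj: SignedAdjacency,
    elements: tuple[str, ...],
    levels: tuple[float, ...] = LADDER_LEVELS,
) -> pd.DataFrame:
    """IN/OUT/ALL link counts for each element across the threshold ladder."""
    rows = []
    for lv in levels:
        sub = apply_threshold(adj, lv)
        for e in elements:
            c = link_counts(sub, e)
            rows.append(
                {
                    "model": model_name(lv),
                    "element": e,
                    "in": c.inward,
                    "out": c.outward,
                    "all": c.all,
                }
            )
    return pd.DataFrame(rows)


def run_experiment(cfg: ExperimentConfig) -> ExperimentBundle:
    """Run the scenario grid through every model and write the result tables."""
    web = cfg.web
    bal = mass_balance(web)
    adj = build_adjacency(web, bal)
    digraphs = {
        model_name(lv): to_signed_digraph(apply_threshold(adj, lv))
        for lv in cfg.ladder_levels
    }

    root = np.random.SeedSequence(cfg.seed)
    tallies: dict[tuple[str, str, int], ResponseTally] = {}
    categories: dict[tuple[str, str, int], dict[str, ResponseCategory]] = {}

    for si, element in enumerate(cfg.scenario_elements):
        for direction in cfg.directions:
            scenario = PressScenario(element=element, direction=direction)
            # one child seed per scenario; level index appended unless coupled
            base = np.random.SeedSequence(cfg.seed, spawn_key=(si, direction % 3))
            if cfg.run_dynamic:
                try:
                    tally = ensemble_tally(
                        web,
                        scenario,
                        n_members=cfg.n_sims,
                        rng=np.random.default_rng(base),
                        max_draws=cfg.ensemble_max_draws,
                        dt=cfg.dt,
                    )
                except Exception as err:
                    raise RuntimeError(
                        f"dynamic ensemble failed for {element} {direction:+d}: {err}"
                    ) from err
                tallies[(DYNAMIC_MODEL, element, direction)] = tally
            for li, lv in enumerate(cfg.ladder_levels):
                key = (si, direction % 3) if cfg.coupled_seeds else (si, direction % 3, li)
                rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))
                try:
                    tally = simulate_press(
                        digraphs[model_name(lv)],
                        scenario,
                        n_accepted=cfg.n_sims,
                        rng=rng,
                        max_draws=cfg.qnm_max_draws,
                    )
                except Exception as err:
                    raise RuntimeError(
                        f"qualitative model {model_name(lv)} failed for "
                        f"{element} {direction:+d}: {err}"
                    ) from err
                tallies[(model_name(lv), element, direction)] = tally

    for key, tally in tallies.items():
        categories[key] = categorize_tally(tally)

    bundle = ExperimentBundle(
        config=cfg, adjacency=adj, tallies=tallies, categories=categories
    )
    if cfg.out_dir is not None:
        _write_bundle(bundle)
    return bundle


def summarize_agreement(bundle: ExperimentBundle) -> pd.DataFrame:
    """Pairwise agreement per scenario: each direction plus a pooled view.

    The pooled row averages the two directions' statistics (the study's
    directional runs were categorically mirror images, so this matches
    reporting a single number per scenario).
    """
    cfg = bundle.config
    missing = [
        (m, e, d)
        for m in bundle.models
        for e in cfg.scenario_elements
        for d in cfg.directions
        if (m, e, d) not in bundle.categories
    ]
    if missing:
        raise ValueError(f"bundle incomplete; missing blocks: {missing}")

    rows = []
    for element in cfg.scenario_elements:
        for ma, mb in combinations(bundle.models, 2):
            per_dir = {}
            for direction in cfg.directions:
                score = model_agreement(
                    bundle.categories[(ma, element, direction)],
                    bundle.categories[(mb, element, direction)],
                )
                per_dir[direction] = score
                rows.append(
                    {
                        "scenario_element": element,
                        "direction": direction,
                        "model_a": ma,
                        "model_b": mb,
                        "percent": score.percent,
                        "percent_with_leans": score.percent_with_leans,
                        "points_total": score.total,
                    }
                )
            rows.append(
                {
                    "scenario_element": element,
                    "direction": 0,  # pooled
                    "model_a": ma,
                    "model_b": mb,
                    "percent": float(np.mean([s.percent for s in per_dir.values()])),
                    "percent_with_leans": float(
                        np.mean([s.percent_with_leans for s in per_dir.values()])
                    ),
                    "points_total": float(np.mean([s.total for s in per_dir.values()])),
                }
            )
    return pd.DataFrame(rows)


def _write_bundle(bundle: ExperimentBundle) -> None:
    cfg = bundle.config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.adjacency.to_csv(out / "adjacency.csv")
    bundle.tally_frame().to_csv(out / "tallies.csv", index=False)
    bundle.category_frame().to_csv(out / "categories.csv", index=False)
    summarize_agreement(bundle).to_csv(out / "agreement.csv", index=False)
    link_count_ladder_table(
        bundle.adjacency, cfg.scenario_elements, cfg.ladder_levels
    ).to_csv(out / "link_counts.csv", index=False)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "n_sims": cfg.n_sims,
        "n_elements": cfg.web.n,
        "scenario_elements": list(cfg.scenario_elements),
        "directions": list(cfg.directions),
        "ladder_levels": list(cfg.ladder_levels),
        "coupled_seeds": cfg.coupled_seeds,
        "run_dynamic": cfg.run_dynamic,
        "models": bundle.models,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file.

    Web source is either ``web: {fixture: <dir>}`` or
    ``web: {synthetic: {<WebSpec fields>}}``.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    src = raw.get("web", {})
    if "fixture" in src:
        web = load_wss28(src["fixture"])
    elif "synthetic" in src:
        web = generate_foodweb(WebSpec(**src["synthetic"]))
    else:
        raise ValueError("config needs web.fixture or web.synthetic")
    kwargs = {}
    for key in (
        "directions",
        "ladder_levels",
        "n_sims",
        "seed",
        "coupled_seeds",
        "run_dynamic",
        "ensemble_max_draws",
        "qnm_max_draws",
        "dt",
    ):
        if key in raw:
            kwargs[key] = tuple(raw[key]) if key in ("directions", "ladder_levels") else raw[key]
    out_dir = raw.get("out_dir")
    return ExperimentConfig(
        web=web,
        scenario_elements=tuple(raw["scenario_elements"]),
        out_dir=Path(out_dir) if out_dir else None,
        **kwargs,
    )
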