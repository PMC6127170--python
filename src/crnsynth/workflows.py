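"""End-to-end design drivers: synthesize -> deduplicate -> score -> optimize
-> rank, with file export.

A run is described by a :class:`RunConfig` (problem family, (N, M) grid,
stutter bound, input set, deadline, optimizer settings).  The pipeline
enumerates every candidate network per (N, M), deduplicates under
specification isomorphism, scores each unique network at unit rates, tunes
its rates with the Metropolis-Hastings optimizer, and ranks by optimized
score.  Results are exported as CRN text files, CSV tables and a JSON
manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CRN, canonical_key, DEFAULT_STATE_CAP
from .specs import (
    Specification,
    division_by_two_spec,
    division_spec,
    majority_spec,
    maximum_spec,
)
from .synthesis import SynthesisProblem, SynthesisResult, enumerate_crns, verify_witness
from .cme import ScoreEvaluator, spec_score
from .optimize import OptimizerConfig, optimize_rates
from .textio import format_crn

__all__ = ["RunConfig", "RankedResults", "build_spec", "run_pipeline",
           "export_results", "derive_seed"]

log = logging.getLogger("crnsynth")

_BUILDERS = {
    "majority": majority_spec,
    "maximum": maximum_spec,
    "division": division_spec,
    "division_by_two": division_by_two_spec,
}


def build_spec(problem: str, input_set=None, t_F: float | None = None) -> Specification:
    """Instantiate a built-in problem family by name."""
    if problem not in _BUILDERS:
        raise ValueError(f"unknown problem {problem!r}; "
                         f"choose from {sorted(_BUILDERS)}")
    kwargs = {}
    if input_set is not None:
        kwargs["input_set"] = [tuple(i) for i in input_set]
    if t_F is not None:
        kwargs["t_F"] = float(t_F)
    return _BUILDERS[problem](**kwargs)


@dataclass
class RunConfig:
    """Configuration of a full design run."""

    problem: str
    grid: list[tuple[int, int]] = field(default_factory=lambda: [(3, 3)])
    stutter_bound: int = 10
    input_set: list[tuple[int, ...]] | None = None
    t_F: float | None = None
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    seed: int = 0
    state_cap: int = DEFAULT_STATE_CAP
    solution_limit: int | None = None
    optimize: bool = True
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "optimizer" in d and isinstance(d["optimizer"], dict):
            opt = dict(d["optimizer"])
            if "log10_rate_bounds" in opt:
                opt["log10_rate_bounds"] = tuple(opt["log10_rate_bounds"])
            d["optimizer"] = OptimizerConfig(**opt)
        d["grid"] = [tuple(g) for g in d.get("grid", [(3, 3)])]
        return cls(**d)


@dataclass
class RankedResults:
    """Unique networks of a run, ordered by optimized score (or unit-rate
    score when optimization is disabled)."""

    config: RunConfig
    table: pd.DataFrame          # one row per unique CRN
    crns: dict[str, CRN]         # id -> representative CRN (unit rates)
    synthesis: list[SynthesisResult]

    def __len__(self) -> int:
        return len(self.table)


def derive_seed(master: int, index: int) -> int:
    """Deterministically split a master seed per optimized network."""
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig) -> RankedResults:
    """Enumerate, deduplicate, score, optimize and rank candidate networks."""
    spec = build_spec(config.problem, config.input_set, config.t_F)
    permute = spec.symmetric_inputs
    rows = []
    crns: dict[str, CRN] = {}
    syntheses = []
    uid = 0
    for (n, m) in config.grid:
        log.info("synthesis: N=%d M=%d K_s=%d", n, m, config.stutter_bound)
        problem = SynthesisProblem(spec, n, m, config.stutter_bound,
                                   solution_limit=config.solution_limit)
        res = enumerate_crns(problem)
        syntheses.append(res)
        for crn, wits in zip(res.crns, res.witnesses):
            if not verify_witness(crn, spec, wits):  # defence against encoding bugs
                raise AssertionError("unsound witness emitted by enumeration")
        log.info("  %d raw solutions (%s)", len(res), res.status)
        seen: dict = {}
        levels: dict = {}
        for crn, lvl in zip(res.crns, res.levels):
            key = canonical_key(crn, permute_inputs=permute)
            if key not in seen:
                seen[key] = crn
                levels[key] = lvl
        log.info("  %d unique under specification isomorphism", len(seen))
        for key, crn in seen.items():
            cid = f"{config.problem}_{n},{m}_{uid}"
            evaluator = ScoreEvaluator(crn, spec, cap=config.state_cap)
            unit = float(evaluator.per_predicate(np.ones(m)).mean())
            row = {
                "id": cid, "n_species": n, "n_reactions": m,
                "canonical_key": repr(key), "level": levels[key],
                "raw_count": sum(
                    1 for c in res.crns
                    if canonical_key(c, permute_inputs=permute) == key),
                "unit_score": unit,
            }
            if config.optimize:
                opt_cfg = OptimizerConfig(
                    burn_in=config.optimizer.burn_in,
                    samples=config.optimizer.samples,
                    log10_rate_bounds=config.optimizer.log10_rate_bounds,
                    proposal_sd=config.optimizer.proposal_sd,
                    seed=derive_seed(config.seed, uid))
                opt = optimize_rates(crn, spec, opt_cfg, evaluator=evaluator)
                row["opt_score"] = opt.best_score
                for i, k in enumerate(opt.k_opt):
                    row[f"k{i}"] = k
            crns[cid] = crn
            rows.append(row)
            uid += 1
    table = pd.DataFrame(rows)
    if len(table):
        by = "opt_score" if config.optimize else "unit_score"
        table = table.sort_values(by, ascending=False, kind="mergesort",
                                  ignore_index=True)
    results = RankedResults(config=config, table=table, crns=crns,
                            synthesis=syntheses)
    if config.output_dir:
        export_results(results, Path(config.output_dir))
    return results


def export_results(results: RankedResults, outdir: Path) -> None:
    """Write CRN files, the ranking table, per-input probability grids and a
    JSON manifest; every CRN file re-parses to an identical network."""
    outdir = Path(outdir)
    (outdir / "crns").mkdir(parents=True, exist_ok=True)
    cfg = results.config
    spec = build_spec(cfg.problem, cfg.input_set, cfg.t_F)
    results.table.to_csv(outdir / "ranking.csv", index=False)
    grids = []
    for _, row in results.table.iterrows():
        cid = row["id"]
        crn = results.crns[cid]
        (outdir / "crns" / f"{cid}.crn").write_text(format_crn(crn))
        rep = spec_score(crn, spec=spec)
        for label, p in zip(rep.labels, rep.per_predicate):
            grids.append({"id": cid, "input": label, "P_unit": float(p)})
    pd.DataFrame(grids).to_csv(outdir / "per_input_unit.csv", index=False)
    manifest = {
        "problem": cfg.problem,
        "grid": [list(g) for g in cfg.grid],
        "stutter_bound": cfg.stutter_bound,
        "input_set": [list(i) for i in spec.input_set],
        "t_F": spec.t_F,
        "seed": cfg.seed,
        "statuses": [s.status for s in results.synthesis],
        "n_raw": [len(s) for s in results.synthesis],
        "n_candidates": [s.n_candidates for s in results.synthesis],
        "n_unique": int(len(results.table)),
        "optimizer": asdict(cfg.optimizer),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
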