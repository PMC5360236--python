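"""Experiment orchestration: runs, replicate sweeps, and file outputs.

A run executes `generations` Wright-Fisher cycles (social life at fixed
parameters, summary, reproduction) under a single RNG stream seeded from
the manifest, so a manifest suffices to bit-reproduce the run. Sweeps
over the encounter rate beta derive one independent, recorded seed per
(beta, replicate) cell from the base seed.

All file outputs are plain text: the manifest as flat key/value lines,
the generation time series and the terminal genotype dump as
tab-separated tables, the optional event log one event per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analytics import GenerationSummary, summarize_generation
from .dynamics import EventRecord, run_generation, write_event_log
from .params import TWO_PRODUCTIVITIES, Params
from .population import (CLASS_NAMES, PopulationState,
                         make_initial_population)
from .reproduction import next_generation


@dataclass
class RunManifest:
    """Everything needed to bit-reproduce one run."""

    params: dict
    seed: int
    replicate: int
    start_generation: int
    end_generation: int
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def lines(self) -> list[str]:
        out = [f"version: {self.version}",
               f"seed: {self.seed}",
               f"replicate: {self.replicate}",
               f"start_generation: {self.start_generation}",
               f"end_generation: {self.end_generation}"]
        out += [f"param.{k}: {v}" for k, v in sorted(self.params.items())]
        out += [f"output.{k}: {v}" for k, v in sorted(self.outputs.items())]
        return out

    def write(self, path: Path) -> None:
        Path(path).write_text("\n".join(self.lines()) + "\n")


@dataclass
class RunResult:
    """In-memory result of one completed run."""

    params: Params
    seed: int
    replicate: int
    manifest: RunManifest
    summaries: pd.DataFrame
    final_state: PopulationState
    events: Optional[list[EventRecord]] = None


def genotype_table(state: PopulationState, params: Params) -> pd.DataFrame:
    """Terminal genotype dump, one individual per row.

    Two-productivity mode: productivity then the four rewards and four
    MARs in canonical (own class, other class) order. Continuum mode:
    productivity, then the reward-network weights (input->hidden row-major,
    then hidden->output, then biases if enabled) and the MAR-network
    weights in the same layout.
    """
    cols: dict[str, np.ndarray] = {"productivity": state.productivity}
    if params.mode == TWO_PRODUCTIVITIES:
        for i in (0, 1):
            for j in (0, 1):
                lbl = f"{CLASS_NAMES[i]}_{CLASS_NAMES[j]}"
                cols[f"r_{lbl}"] = state.rewards[:, i, j]
                cols[f"mar_{lbl}"] = state.mars[:, i, j]
        return pd.DataFrame(cols)
    for name, w in (("rw", state.reward_weights),
                    ("mw", state.mar_weights)):
        for k in range(w.shape[1]):
            cols[f"{name}{k}"] = w[:, k]
    return pd.DataFrame(cols)


def run_experiment(params: Params, *, out_dir: Optional[str | Path] = None,
                   replicate: int = 0, record_every: int = 10,
                   keep_events: bool = False) -> RunResult:
    """Run one full experiment: generations of social life + reproduction.

    Generation g's summary is taken after its social life and before
    reproduction; summaries are recorded every `record_every` generations
    and always at the final generation. With `out_dir` set, writes
    manifest.txt, summary.tsv, genotypes.tsv and (if `keep_events`)
    events.tsv. Deterministic under a fixed (seed, replicate) pair.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence((params.seed,
                                                        replicate)))
    state = make_initial_population(params, rng)
    events: Optional[list[EventRecord]] = [] if keep_events else None
    rows = []
    for g in range(params.generations):
        stats = run_generation(state, params, rng, log=events)
        last = g == params.generations - 1
        if g % record_every == 0 or last:
            rows.append(summarize_generation(state, params, stats).to_row())
        if not last:
            state = next_generation(state, params, rng)
    summaries = pd.DataFrame(rows)
    manifest = RunManifest(params=params.to_dict(), seed=params.seed,
                           replicate=replicate, start_generation=0,
                           end_generation=params.generations - 1)
    result = RunResult(params=params, seed=params.seed, replicate=replicate,
                       manifest=manifest, summaries=summaries,
                       final_state=state, events=events)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"summary": out / "summary.tsv",
                 "genotypes": out / "genotypes.tsv",
                 "manifest": out / "manifest.txt"}
        summaries.to_csv(paths["summary"], sep="\t", index=False,
                         float_format="%.10g")
        genotype_table(state, params).to_csv(
            paths["genotypes"], sep="\t", index=False, float_format="%.10g")
        if keep_events:
            paths["events"] = out / "events.tsv"
            write_event_log(events, paths["events"])
        # record names relative to the run directory so a relocated run
        # directory stays self-describing and byte-reproducible
        manifest.outputs = {k: v.name for k, v in paths.items()
                            if k != "manifest"}
        manifest.write(paths["manifest"])
    return result


def derive_seed(base_seed: int, beta_index: int, replicate: int) -> int:
    """Deterministic seed mix for one sweep cell, recorded in its manifest."""
    ss = np.random.SeedSequence((base_seed, beta_index, replicate))
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


def sweep_beta(params: Params, beta_values: Sequence[float],
               replicates: int = 1, *,
               out_dir: Optional[str | Path] = None,
               record_every: int = 10) -> list[RunResult]:
    """Independent runs over an encounter-rate grid.

    Returns one RunResult per (beta, replicate), each with its own derived
    seed; feeds terminal_reward_distribution for the choosiness-cost
    analysis.
    """
    results = []
    for bi, beta in enumerate(beta_values):
        for rep in range(replicates):
            seed = derive_seed(params.seed, bi, rep)
            p = params.replace(beta=beta, seed=seed)
            sub = (Path(out_dir) / f"beta{bi}_rep{rep}"
                   if out_dir is not None else None)
            results.append(run_experiment(p, out_dir=sub, replicate=rep,
                                          record_every=record_every))
    return results


def aggregate_summaries(results: Sequence[RunResult],
                        lower: float = 0.05,
                        upper: float = 0.95) -> pd.DataFrame:
    """Across-replicate aggregation of generation time series.

    Returns, per generation and numeric column, the mean and the central
    band given by the (lower, upper) quantiles over runs.
    """
    frames = [r.summaries.assign(_run=i) for i, r in enumerate(results)]
    stacked = pd.concat(frames, ignore_index=True)
    value_cols = [c for c in stacked.columns
                  if c not in ("generation", "_run")]
    grouped = stacked.groupby("generation")[value_cols]
    agg = grouped.agg(["mean",
                       lambda s: s.quantile(lower),
                       lambda s: s.quantile(upper)])
    agg.columns = [f"{c}_{stat}" for c, stat in
                   ((c, {"mean": "mean", "<lambda_0>": "lo",
                         "<lambda_1>": "hi"}[s]) for c, s in agg.columns)]
    return agg.reset_index()
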