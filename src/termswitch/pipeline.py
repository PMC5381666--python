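"""End-to-end orchestration: data -> filters -> reconstruction -> switches
-> statistics -> report.

A :class:`RunConfig` either points at existing inputs (analyze mode: tree,
alignment manifest, structure file, optional gene annotations) or carries
simulate-block parameters (simulate mode). :func:`run_full_analysis`
executes the stages in order with per-stage logging (every log row
satisfies in - dropped = out) and returns a :class:`RunSummary`;
:func:`write_report` serializes it as a JSON record plus TSV tables whose
header comments name the producing stage and the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._tree import IndexedTree, read_newick
from .alignment import (FilterThresholds, TerminatorAlignment,
                        apply_alignment_filters, read_alignment_directory,
                        retain_column_pairs)
from .ancestral import GeneReconstruction, reconstruct_alignment
from .simulate import PairFitnessModel, SimulationConfig, generate_dataset
from .switches import SwitchEvent, analyze_pair, compensation_distance
from .stats import (BidirectionalResult, PermutationNull, SwitchSummary,
                    _column_variable, bidirectional_analysis,
                    binomial_two_tailed, compare_compensation_distances,
                    conservation_summary, pair_fate_table, permutation_null,
                    positional_variability)

__all__ = ["RunConfig", "RunSummary", "StageError", "run_full_analysis",
           "write_report", "STAGES"]

STAGES = ("input", "filter", "reconstruct", "switches", "stats", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and gene context."""

    def __init__(self, stage: str, message: str, gene_id: str = ""):
        self.stage = stage
        self.gene_id = gene_id
        ctx = f" (gene {gene_id})" if gene_id else ""
        super().__init__(f"[{stage}]{ctx} {message}")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``mode`` is 'simulate' (terminators are generated with the simulate
    block) or 'analyze' (tree/manifest/structures paths must exist). The
    seed drives simulation and the permutation null.
    """

    mode: str = "simulate"
    seed: int = 0
    out_dir: str = "run_out"
    # analyze-mode inputs
    tree_path: Optional[str] = None
    manifest_path: Optional[str] = None
    structures_path: Optional[str] = None
    annotations_path: Optional[str] = None
    # simulate-mode parameters
    n_strains: int = 25
    n_genes: int = 100
    depth: Optional[float] = None          # None = simulator default
    gu_acceptance: float = 0.3
    mismatch_acceptance: float = 0.01
    # thresholds
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    posterior_threshold: float = 0.8
    n_permutations: int = 100_000
    max_gap: int = 200

    def __post_init__(self):
        if self.mode not in ("simulate", "analyze"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.mode == "analyze":
            for name in ("tree_path", "manifest_path", "structures_path"):
                p = getattr(self, name)
                if p is None or not os.path.exists(p):
                    raise ValueError(f"analyze mode: {name} missing "
                                     f"or does not exist: {p!r}")
            if (self.annotations_path is not None
                    and not os.path.exists(self.annotations_path)):
                raise ValueError(
                    f"annotations_path does not exist: "
                    f"{self.annotations_path!r}")
        if not (0.0 < self.posterior_threshold <= 1.0):
            raise ValueError("posterior_threshold must be in (0,1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = FilterThresholds(**raw["thresholds"])
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunSummary:
    """Everything a run produced, ready for reporting."""

    config: RunConfig
    stage_log: list[dict]
    headline: dict
    switch_table: pd.DataFrame
    conservation: pd.DataFrame
    pair_fates: pd.DataFrame
    positional: dict
    null: Optional[PermutationNull]
    bidirectional: Optional[BidirectionalResult]

    @property
    def config_hash(self) -> str:
        return self.config.config_hash


def _log(stage_log: list, stage: str, what: str,
         n_in: int, n_dropped: int) -> None:
    if n_dropped < 0 or n_dropped > n_in:
        raise StageError(stage, f"inconsistent counts for {what}: "
                                f"in={n_in} dropped={n_dropped}")
    stage_log.append(dict(stage=stage, item=what, n_in=n_in,
                          n_dropped=n_dropped, n_out=n_in - n_dropped))


def _load_inputs(cfg: RunConfig, stage_log: list):
    if cfg.mode == "simulate":
        model = PairFitnessModel(acceptance_gu=cfg.gu_acceptance,
                                 acceptance_mismatch=cfg.mismatch_acceptance)
        sim_kwargs = dict(n_strains=cfg.n_strains, n_genes=cfg.n_genes,
                          model=model)
        if cfg.depth is not None:
            sim_kwargs["depth"] = cfg.depth
        sim_cfg = SimulationConfig(**sim_kwargs)
        ds = generate_dataset(sim_cfg, seed=cfg.seed)
        data_dir = os.path.join(cfg.out_dir, "data")
        ds.write(data_dir)
        alns, tree, ann = ds.alignments, ds.tree, ds.annotations
    else:
        tree = read_newick(cfg.tree_path)
        alns = read_alignment_directory(cfg.manifest_path,
                                        cfg.structures_path)
        ann = None
        if cfg.annotations_path is not None:
            ann = pd.read_csv(cfg.annotations_path, sep="\t", comment="#")
    _log(stage_log, "input", "genes", len(alns), 0)
    return tree, alns, ann


def _filter_stage(cfg: RunConfig, alns, stage_log: list):
    kept_alns = []
    for aln in alns:
        try:
            _, retained = apply_alignment_filters(aln, cfg.thresholds)
        except Exception as exc:
            raise StageError("filter", str(exc), aln.gene_id) from exc
        if retained:
            kept_alns.append(aln)
    _log(stage_log, "filter", "genes", len(alns), len(alns) - len(kept_alns))
    n_pairs_in = sum(len(a.column_pairs) for a in kept_alns)
    out = [retain_column_pairs(a) for a in kept_alns]
    out = [a for a in out if a.column_pairs]
    n_pairs_out = sum(len(a.column_pairs) for a in out)
    _log(stage_log, "filter", "column_pairs", n_pairs_in,
         n_pairs_in - n_pairs_out)
    return out


def _switch_stage(tree: IndexedTree, alns,
                  recs: dict[str, GeneReconstruction],
                  stage_log: list) -> tuple[list[SwitchEvent], list]:
    events: list[SwitchEvent] = []
    distances = []   # (kind, intermediate, distance)
    n_pairs = 0
    for aln in alns:
        rec = recs[aln.gene_id]
        res = rec.resolved
        for (l, r) in aln.column_pairs:
            n_pairs += 1
            a, b = res[l].tolist(), res[r].tolist()
            js = [x * 4 + y if (x >= 0 and y >= 0) else -1
                  for x, y in zip(a, b)]
            try:
                evs = analyze_pair(tree, js, gene_id=aln.gene_id,
                                   left_col=l, right_col=r)
            except Exception as exc:
                raise StageError("switches", str(exc), aln.gene_id) from exc
            for ev in evs:
                d = compensation_distance(ev, tree)
                if d is not None:
                    distances.append((ev.kind, ev.intermediate, d))
            events.extend(evs)
    _log(stage_log, "switches", "column_pairs", n_pairs, 0)
    _log(stage_log, "switches", "switch_events", len(events), 0)
    return events, distances


def _polymorphic_pool(tree: IndexedTree, alns,
                      recs: dict[str, GeneReconstruction]
                      ) -> tuple[np.ndarray, int]:
    """Both columns of every interacting pair with >=1 variable column.

    Returns the (n_columns, n_nodes) pool of resolved states and the
    number of contributing ("active") pairs, which sets the permutation
    batch size.
    """
    pool = []
    n_active = 0
    for aln in alns:
        res = recs[aln.gene_id].resolved
        for (l, r) in aln.column_pairs:
            if _column_variable(aln, l) or _column_variable(aln, r):
                n_active += 1
                pool.append(res[l])
                pool.append(res[r])
    arr = np.asarray(pool) if pool else np.empty((0, tree.n_nodes), int)
    return arr, n_active


def _stats_stage(cfg: RunConfig, tree, alns, recs, events, distances,
                 ann, stage_log: list):
    summary = SwitchSummary.from_events(events)
    n_pairs = sum(len(a.column_pairs) for a in alns)
    pool, n_active = _polymorphic_pool(tree, alns, recs)
    null = None
    if pool.shape[0] >= 2:
        null = permutation_null(tree, pool,
                                n_permutations=cfg.n_permutations,
                                seed=cfg.seed,
                                batch_size=max(n_active, 1))
    # GU vs AC among observed AU<>GC intermediates (types 2 and 3)
    n_gu = sum(1 for ev in events
               if ev.kind == "AU<>GC" and ev.switch_type in (2, 3)
               and ev.intermediate == "GU")
    n_ac = sum(1 for ev in events
               if ev.kind == "AU<>GC" and ev.switch_type in (2, 3)
               and ev.intermediate == "AC")
    p_gu = binomial_two_tailed(n_gu, n_gu + n_ac, 0.5) \
        if (n_gu + n_ac) > 0 else math.nan
    d_gu = [d for k, i, d in distances if i in ("GU", "UG")]
    d_other = [d for k, i, d in distances if i not in ("GU", "UG", "UNKNOWN")]
    if d_gu and d_other:
        p_dist, mean_gu, mean_other = compare_compensation_distances(
            d_gu, d_other)
    else:
        p_dist = mean_gu = mean_other = math.nan
    obs_tir = summary.tir
    obs_ratio = summary.intermediate_observed_ratio
    headline = {
        "n_genes_analyzed": len(alns),
        "n_column_pairs": n_pairs,
        "n_switches": summary.total,
        "counts_by_type": {str(t + 1): int(c)
                           for t, c in enumerate(summary.n_by_type)},
        "counts_by_kind": {k: int(v) for k, v in summary.n_by_kind.items()},
        "tir": obs_tir,
        "intermediate_observed_ratio": obs_ratio,
        "gu_intermediates": n_gu, "ac_intermediates": n_ac,
        "p_gu_vs_ac": p_gu,
        "mean_distance_gu": mean_gu, "mean_distance_other": mean_other,
        "p_distance_gu_vs_other": p_dist,
        "n_polymorphic_columns": int(pool.shape[0]),
    }
    if null is not None:
        headline.update({
            "null_expected_counts": [float(x)
                                     for x in null.expected_counts(n_pairs)],
            "null_expected_tir": null.expected_tir,
            "null_tir_interval": list(null.interval("tir")),
            "null_ratio_interval": list(null.interval("ratio")),
            "tir_significant": (null.significant(obs_tir, "tir")
                                if math.isfinite(obs_tir) else False),
            "ratio_significant": (null.significant(obs_ratio, "ratio")
                                  if math.isfinite(obs_ratio) else False),
        })
    conservation = conservation_summary(alns)
    fates = pair_fate_table(alns, recs)
    positional = positional_variability(alns, recs)
    bidir = None
    if ann is not None and "term_start" in getattr(ann, "columns", ()):
        bidir = bidirectional_analysis(ann, alns, max_gap=cfg.max_gap,
                                       thresholds=cfg.thresholds)
        headline["bidirectional_p_values"] = {
            k: float(v) for k, v in bidir.p_values.items()}
    _log(stage_log, "stats", "switch_events", summary.total, 0)
    return headline, summary, conservation, fates, positional, null, bidir


def _switch_table(tree: IndexedTree, events: Sequence[SwitchEvent]
                  ) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(dict(
            gene_id=ev.gene_id, left_col=ev.left_col, right_col=ev.right_col,
            state_a=ev.state_a, state_b=ev.state_b, kind=ev.kind,
            switch_type=ev.switch_type, intermediate=ev.intermediate,
            lca_state=ev.lca_state,
            branch_left=ev.event_branches[0] or "",
            branch_right=ev.event_branches[1] or "",
            distance=(lambda d: "" if d is None else d)(
                compensation_distance(ev, tree)),
            flags=";".join(ev.flags)))
    cols = ["gene_id", "left_col", "right_col", "state_a", "state_b",
            "kind", "switch_type", "intermediate", "lca_state",
            "branch_left", "branch_right", "distance", "flags"]
    return pd.DataFrame(rows, columns=cols)


def run_full_analysis(config: RunConfig,
                      stop_after: str = "report") -> RunSummary:
    """Execute the pipeline stages in order and return the run summary.

    ``stop_after`` truncates the run after the named stage (used by the
    per-stage CLI subcommands); the summary then carries empty downstream
    products. Any stage error is re-raised as :class:`StageError` with
    stage and gene context.
    """
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    os.makedirs(config.out_dir, exist_ok=True)
    stage_log: list[dict] = []
    empty = RunSummary(config=config, stage_log=stage_log, headline={},
                       switch_table=pd.DataFrame(),
                       conservation=pd.DataFrame(),
                       pair_fates=pd.DataFrame(), positional={},
                       null=None, bidirectional=None)

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    tree, alns, ann = _stage("input", _load_inputs, config, stage_log)
    if stop_after == "input":
        return empty
    alns = _stage("filter", _filter_stage, config, alns, stage_log)
    if stop_after == "filter":
        return empty

    def _reconstruct():
        recs = {}
        for aln in alns:
            try:
                recs[aln.gene_id] = reconstruct_alignment(
                    tree, aln, threshold=config.posterior_threshold)
            except Exception as exc:
                raise StageError("reconstruct", str(exc),
                                 aln.gene_id) from exc
        _log(stage_log, "reconstruct", "genes", len(alns), 0)
        return recs

    recs = _reconstruct()
    if stop_after == "reconstruct":
        return empty
    events, distances = _switch_stage(tree, alns, recs, stage_log)
    summary_table = _switch_table(tree, events)
    if stop_after == "switches":
        return dataclasses.replace(empty, switch_table=summary_table)
    headline, _, conservation, fates, positional, null, bidir = _stage(
        "stats", _stats_stage, config, tree, alns, recs, events, distances,
        ann, stage_log)
    result = RunSummary(config=config, stage_log=stage_log,
                        headline=headline, switch_table=summary_table,
                        conservation=conservation, pair_fates=fates,
                        positional=positional, null=null,
                        bidirectional=bidir)
    if stop_after == "stats":
        return result
    _stage("report", write_report, result, config.out_dir)
    return result


def _json_safe(x):
    if isinstance(x, dict):
        return {k: _json_safe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_json_safe(v) for v in x]
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating, float)):
        f = float(x)
        if math.isnan(f):
            return None
        if math.isinf(f):
            return "inf" if f > 0 else "-inf"
        return f
    return x


def _write_tsv(df: pd.DataFrame, path: str, stage: str, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n# config_hash: {chash}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_report(summary: RunSummary, destination: str) -> None:
    """Write the JSON run record and the per-table TSVs.

    Files: run_summary.json, stage_log.tsv, switches.tsv,
    conservation.tsv, pair_fates.tsv, positional_tables.tsv,
    null_distribution.tsv (batch TIR/ratio samples) and, when
    annotations were available, bidirectional.tsv.
    """
    os.makedirs(destination, exist_ok=True)
    chash = summary.config_hash
    record = {
        "config": _json_safe(summary.config.to_dict()),
        "config_hash": chash,
        "stage_log": summary.stage_log,
        "headline": _json_safe(summary.headline),
    }
    with open(os.path.join(destination, "run_summary.json"), "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _write_tsv(pd.DataFrame(summary.stage_log),
               os.path.join(destination, "stage_log.tsv"), "all", chash)
    _write_tsv(summary.switch_table,
               os.path.join(destination, "switches.tsv"), "switches", chash)
    _write_tsv(summary.conservation,
               os.path.join(destination, "conservation.tsv"), "stats", chash)
    _write_tsv(summary.pair_fates,
               os.path.join(destination, "pair_fates.tsv"), "stats", chash)
    pos_rows = [dict(table=name, variable_1=int(t[0, 0]),
                     invariant_1=int(t[0, 1]), variable_2=int(t[1, 0]),
                     invariant_2=int(t[1, 1]), p_value=p)
                for name, (t, p) in summary.positional.items()]
    _write_tsv(pd.DataFrame(pos_rows),
               os.path.join(destination, "positional_tables.tsv"),
               "stats", chash)
    if summary.null is not None:
        n = min(len(summary.null.tir_samples),
                len(summary.null.ratio_samples))
        nd = pd.DataFrame(dict(batch=np.arange(n),
                               tir=summary.null.tir_samples[:n],
                               ratio=summary.null.ratio_samples[:n]))
        _write_tsv(nd, os.path.join(destination, "null_distribution.tsv"),
                   "stats", chash)
    if summary.bidirectional is not None:
        b = summary.bidirectional
        rows = [dict(category=k, variable=int(t[0, 0]),
                     invariant=int(t[0, 1]),
                     cooriented_variable=int(t[1, 0]),
                     cooriented_invariant=int(t[1, 1]),
                     p_value=b.p_values[k])
                for k, t in b.tables.items()]
        _write_tsv(pd.DataFrame(rows),
                   os.path.join(destination, "bidirectional.tsv"),
                   "stats", chash)
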