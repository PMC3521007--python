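"""End-to-end orchestration: screen → alignment selection → inference →
combination → HGT calling, with every intermediate artifact written to a
run directory and a deterministic JSON report at the end.

The stages are pure functions of their inputs plus the configured seeds,
so rerunning an identical configuration yields a byte-identical report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .alignment import Alignment, filter_columns, mos_scores, read_alignment, write_alignment
from .call import HGTReport, confirm_candidates, group_events, summarize
from .combine import combine_method_trees, support_table
from .infer import bootstrap
from .screen import (
    HGTCandidate,
    ScreenParams,
    detect_foreign_leaves,
    ensure_rooted,
    filter_by_length,
    populate_fragment_lengths,
)
from .taxonomy import build_kingdom_map, read_taxonomy_table
from .trees import Tree, parse_newick, write_newick

__all__ = ["RunConfig", "run_pipeline", "run_in_memory", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    tree_path: str
    taxonomy_path: str
    alignment_paths: tuple[str, ...]
    output_dir: str
    ml_tree_path: Optional[str] = None
    sequences_path: Optional[str] = None
    screen: ScreenParams = field(default_factory=ScreenParams)
    methods: tuple[str, ...] = ("nj", "mp")
    bootstrap_n: int = 100
    seed: int = 0
    column_threshold: float = 0.93
    alignment_format: str = "fasta"

    def validate(self) -> None:
        for label, path in [
            ("tree", self.tree_path),
            ("taxonomy", self.taxonomy_path),
            *(("alignment", p) for p in self.alignment_paths),
        ]:
            if not Path(path).exists():
                raise PipelineError("config", f"{label} input missing: {path}")
        if self.ml_tree_path and not Path(self.ml_tree_path).exists():
            raise PipelineError("config", f"ML tree missing: {self.ml_tree_path}")
        if len(self.alignment_paths) < 2:
            raise PipelineError(
                "config", "need an ensemble of at least two alignments"
            )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> HGTReport:
    """Execute the full pipeline from files; see :class:`RunConfig`."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    tree = _stage("read-tree")(lambda: parse_newick(Path(config.tree_path).read_text()))()
    records = _stage("read-taxonomy")(read_taxonomy_table)(config.taxonomy_path)
    kingdoms = build_kingdom_map(records)
    ensemble = _stage("read-alignments")(
        lambda: [
            read_alignment(p, config.alignment_format)
            for p in config.alignment_paths
        ]
    )()

    report = run_in_memory(
        tree=tree,
        kingdoms=kingdoms,
        ensemble=ensemble,
        params=config.screen,
        methods=config.methods,
        bootstrap_n=config.bootstrap_n,
        seed=config.seed,
        column_threshold=config.column_threshold,
        ml_tree=_read_optional_tree(config.ml_tree_path),
        outdir=outdir,
    )
    return report


def _read_optional_tree(path: Optional[str]) -> Optional[Tree]:
    if not path:
        return None
    return parse_newick(Path(path).read_text())


def run_in_memory(
    tree: Tree,
    kingdoms: Mapping[str, str],
    ensemble: Sequence[Alignment],
    params: Optional[ScreenParams] = None,
    methods: Sequence[str] = ("nj", "mp"),
    bootstrap_n: int = 100,
    seed: int = 0,
    column_threshold: float = 0.93,
    ml_tree: Optional[Tree] = None,
    outdir: Optional[Path] = None,
) -> HGTReport:
    """The pipeline on in-memory objects (the file layer is optional)."""
    params = params or ScreenParams()

    # Stage 1: screen the reference tree
    candidates = _stage("screen")(detect_foreign_leaves)(tree, kingdoms, params)
    logger.info("screen: %d candidate leaves", len(candidates))
    aligned_lengths = {
        sid: ensemble[0].aligned_length(sid) for sid in ensemble[0].ids
    }
    candidates = populate_fragment_lengths(candidates, aligned_lengths)
    candidates = _stage("screen")(filter_by_length)(candidates, params)

    # Stage 2: alignment ensemble selection and column filtering
    scores, best = _stage("score-alignments")(mos_scores)(ensemble)
    chosen = ensemble[best]
    filtered, column_scores = _stage("filter-columns")(filter_columns)(
        chosen, ensemble, column_threshold
    )
    logger.info(
        "alignments: MOS-best index %d, %d/%d columns kept",
        best,
        filtered.n_cols,
        chosen.n_cols,
    )

    # Stage 3: per-method inference with bootstrap
    method_trees: list[tuple[str, Tree]] = []
    boot_results = {}
    for k, method in enumerate(methods):
        res = _stage(f"infer-{method}")(bootstrap)(
            filtered, method=method, n=bootstrap_n, seed=seed + k
        )
        boot_results[method] = res
        method_trees.append((method.upper(), res.tree))
    if ml_tree is not None:
        method_trees.insert(0, ("ML", ml_tree))

    # Stage 4: strict-intersection combination
    combined = _stage("combine")(combine_method_trees)(method_trees)

    # Stage 5: confirmation, events, report — the combined tree inherits
    # the screening tree's rooting via its root bipartition.
    rooted_input = _stage("screen")(ensure_rooted)(tree, params)
    root_split = {
        lf.label for lf in rooted_input.root.children[0].leaves()
    } if rooted_input.root.children else None
    statuses = _stage("call")(confirm_candidates)(
        combined, kingdoms, candidates, params, root_split=root_split
    )
    confirmed = {
        c.leaf_id: (c.native_kingdom, c.host_kingdom)
        for c in candidates
        if statuses.get(c.leaf_id) == "confirmed"
    }
    events = _stage("call")(group_events)(
        combined, confirmed, params, root_split=root_split
    )
    report = _stage("call")(summarize)(
        statuses,
        candidates,
        events,
        params,
        extra_params={
            "methods": list(methods) + (["ml"] if ml_tree is not None else []),
            "bootstrap_n": bootstrap_n,
            "seed": seed,
            "column_threshold": column_threshold,
            "mos_scores": [round(s, 6) for s in scores],
            "mos_selected": best,
            "columns_kept": filtered.n_cols,
            "columns_total": chosen.n_cols,
        },
    )

    if outdir is not None:
        _write_artifacts(
            outdir,
            tree,
            params,
            candidates,
            scores,
            best,
            filtered,
            column_scores,
            method_trees,
            combined,
            report,
        )
    return report


def _write_artifacts(
    outdir: Path,
    tree: Tree,
    params: ScreenParams,
    candidates: Sequence[HGTCandidate],
    scores: Sequence[float],
    best: int,
    filtered: Alignment,
    column_scores: Sequence[float],
    method_trees: Sequence[tuple[str, Tree]],
    combined: Tree,
    report: HGTReport,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rooted = ensure_rooted(tree, params)
    (outdir / "input_tree.rooted.nwk").write_text(write_newick(rooted) + "\n")
    pd.DataFrame(
        [
            {
                "id": c.leaf_id,
                "native": c.native_kingdom,
                "host": c.host_kingdom,
                "clade_size": c.host_clade_size,
                "purity": c.purity,
                "length": c.fragment_length,
                "status": report.statuses.get(c.leaf_id, c.status),
                "note": c.note,
            }
            for c in candidates
        ],
        columns=[
            "id", "native", "host", "clade_size", "purity", "length", "status", "note",
        ],
    ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"alignment_index": range(len(scores)), "mos": list(scores)}
    ).assign(selected=lambda df: df.alignment_index == best).to_csv(
        outdir / "mos.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"column": range(len(column_scores)), "score": list(column_scores)}
    ).to_csv(outdir / "column_scores.tsv", sep="\t", index=False)
    write_alignment(filtered, str(outdir / "alignment.filtered.fasta"))
    for name, t in method_trees:
        (outdir / f"tree.{name.lower()}.nwk").write_text(write_newick(t) + "\n")
    (outdir / "tree.combined.nwk").write_text(write_newick(combined) + "\n")
    pd.DataFrame(support_table(combined)).to_csv(
        outdir / "supports.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "members": ";".join(e.members),
                "source": e.source_kingdom,
                "host": e.host_kingdom,
                "size": e.size,
                "ancient": e.ancient,
            }
            for e in report.events
        ],
        columns=["members", "source", "host", "size", "ancient"],
    ).to_csv(outdir / "events.tsv", sep="\t", index=False)
    (outdir / "report.json").write_text(report.to_json() + "\n")
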