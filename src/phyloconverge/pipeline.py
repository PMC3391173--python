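"""End-to-end analysis: characters on trees, signal tests, convergence test,
tree incongruence.

One call runs, for every input tree: parsimony step counts and consistency
indices for the niche and host-group characters, tip-permutation
(Maddison–Slatkin) tests for both, the convergent-pair count with its
random-tree null test, and — when at least two trees share a tip set — the
pairwise partition-metric matrix with a principal coordinates embedding.
All randomness is derived deterministically from one base seed, and the
report is plain JSON-serializable data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import __version__
from .chardata import (
    TaxonTable,
    character_from_table,
    read_alias_map,
    read_taxon_table,
    table1_fixture,
)
from .convergence import convergence_null_test, convergent_pair_count, max_convergent_pairs
from .parsimony import fitch_steps
from .randomization import maddison_slatkin_test
from .treedist import distance_matrix, pcoa
from .treeio import PhyloTree, read_newick_file

logger = logging.getLogger("phyloconverge")

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "derive_seed"]


def derive_seed(base_seed: int, *key) -> int:
    """Deterministic sub-seed (< 2**31) for one named pipeline component."""

    def stable(k) -> int:
        if isinstance(k, int):
            return k % (2**31)
        digest = hashlib.sha256(str(k).encode("utf-8")).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    h = np.random.SeedSequence([int(base_seed) % (2**31)] + [stable(k) for k in key])
    return int(h.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    tree_files: list = field(default_factory=list)
    trees: Optional[list] = None  # pre-parsed PhyloTree inputs
    tree_labels: Optional[list] = None
    table_path: Optional[str] = None  # None -> packaged fixture table
    alias_path: Optional[str] = None
    seed: int = 0
    n_permutations: int = 1000
    n_null_trees: int = 100
    null_model: str = "pda_uniform"
    polytomy_mode: str = "strict"
    convention: str = "plus_one"
    fields: tuple = ("niche", "host_group")


@dataclass
class AnalysisReport:
    data: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.data, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(json.loads(text))


def _load_trees(config: PipelineConfig) -> tuple[list[PhyloTree], list[str]]:
    trees, labels = [], []
    if config.trees:
        trees = list(config.trees)
        labels = list(config.tree_labels or [f"tree{i + 1}" for i in range(len(trees))])
    for path in config.tree_files:
        batch = read_newick_file(path)
        for j, t in enumerate(batch):
            trees.append(t)
            suffix = f"#{j + 1}" if len(batch) > 1 else ""
            labels.append(f"{path}{suffix}")
    if not trees:
        raise ValueError("no input trees: provide tree_files or trees")
    return trees, labels


def _character_analysis(tree, table, fields, alias, seed, n_reps, convention):
    out = {}
    for fld in fields:
        char = character_from_table(table, fld, taxa=_aliased(tree.tip_labels, alias))
        # re-key states to the tree's own tip labels (alias targets may differ)
        char = type(char)(dict(zip(tree.tip_labels, char.assignments.values())))
        sc = fitch_steps(tree, char)
        ms = maddison_slatkin_test(
            tree,
            char,
            n_reps=n_reps,
            seed=derive_seed(seed, "ms", fld),
            convention=convention,
        )
        out[fld] = {
            "steps": sc.steps,
            "min_possible": sc.min_possible,
            "consistency_index": sc.consistency_index,
            "maddison_slatkin": ms.summary(),
        }
    return out


def _aliased(tips, alias):
    if not alias:
        return list(tips)
    from .chardata import _norm_label

    return [alias.get(_norm_label(t), t) for t in tips]


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run every analysis stage; any stage failure aborts with a stage-named
    error."""
    t0 = time.time()
    stage = "load-table"
    try:
        if config.table_path is None:
            table = table1_fixture()
        else:
            table = read_taxon_table(config.table_path)
        alias = read_alias_map(config.alias_path) if config.alias_path else None

        stage = "load-trees"
        trees, labels = _load_trees(config)
        logger.info("loaded %d tree(s), table with %d taxa", len(trees), len(table))

        stage = "max-pairs"
        max_pairs = max_convergent_pairs(table)

        per_tree = {}
        for label, tree in zip(labels, trees):
            stage = f"characters[{label}]"
            chars = _character_analysis(
                tree,
                table,
                config.fields,
                alias,
                config.seed,
                config.n_permutations,
                config.convention,
            )
            stage = f"convergence[{label}]"
            count, pairs = convergent_pair_count(
                tree, table, polytomy_mode=config.polytomy_mode, alias=alias
            )
            null = convergence_null_test(
                table,
                tree,
                n_trees=config.n_null_trees,
                model=config.null_model,
                seed=derive_seed(config.seed, "convergence", label),
                polytomy_mode=config.polytomy_mode,
                alias=alias,
                convention=config.convention,
            )
            per_tree[label] = {
                "n_tips": tree.n_tips,
                "characters": chars,
                "convergent_pairs": {
                    "count": count,
                    "pairs": [vars(p) for p in pairs],
                    "null_test": null.summary(),
                },
            }
            logger.info("tree %s: %d convergent pairs", label, count)

        tree_space = None
        if len(trees) >= 2 and all(
            set(t.tip_labels) == set(trees[0].tip_labels) for t in trees
        ):
            stage = "treedist"
            dm = distance_matrix(trees, labels=labels)
            emb = pcoa(dm)
            tree_space = {
                "labels": labels,
                "distance_matrix": dm.values.tolist(),
                "eigenvalues": emb.eigenvalues.tolist(),
                "percent_variance": emb.percent_variance.tolist(),
                "coordinates": emb.coordinates.tolist(),
                "negative_eigenvalues": emb.negative_eigenvalue_flag,
            }

        report = {
            "version": __version__,
            "config": {
                "seed": config.seed,
                "n_permutations": config.n_permutations,
                "n_null_trees": config.n_null_trees,
                "null_model": config.null_model,
                "polytomy_mode": config.polytomy_mode,
                "convention": config.convention,
                "table": config.table_path or "fixture:table1",
            },
            "table": {
                "n_taxa": len(table),
                "n_annotated": len(table.annotated),
                "host_groups": table.host_groups(),
            },
            "max_convergent_pairs": max_pairs,
            "trees": per_tree,
            "tree_space": tree_space,
            "runtime_seconds": round(time.time() - t0, 3),
        }
        return AnalysisReport(report)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
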