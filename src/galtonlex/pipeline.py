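"""End-to-end analysis: wordlists + groups + traits -> Mantel + tree report.

Stages, per lexical measure: variety-level distance matrix -> group
(province) aggregation -> alignment with the trait table (complete-case) ->
trait-difference matrix -> permutation Mantel test; plus UPGMA clustering
of the variety-level matrix with a top-k branch cut.  Every intermediate
matrix is written to the output directory and the run is summarised in a
JSON report that records all parameters and seeds needed to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .aggregation import align_matrices, group_distance_matrix, trait_difference_matrix
from .clustering import top_branches, upgma
from .distances import MEASURES, pairwise_matrix
from .lexical_io import (
    GroupMap,
    TraitTable,
    ValidationError,
    Wordlist,
    write_matrix,
)
from .mantel import MantelResult, mantel_test

logger = logging.getLogger("galtonlex")


class StageError(RuntimeError):
    """Wraps an upstream failure with the name of the pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"[{stage}] {cause}")


@dataclass
class MeasureResult:
    measure: str
    mantel: MantelResult
    clusters: dict[str, int]
    tree_newick: str
    files: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "mantel": self.mantel.to_dict(),
            "clusters": self.clusters,
            "tree_newick": self.tree_newick,
            "files": self.files,
        }


@dataclass
class RunReport:
    """Everything needed to reproduce and interpret one analysis run."""

    version: str
    seed: int
    n_perm: int
    tail: str
    k: int
    linkage: str
    input_digests: dict[str, str]
    n_varieties: int
    n_groups: int
    varieties_dropped: list[str]
    groups_dropped: list[str]
    results: dict[str, MeasureResult]

    def to_dict(self) -> dict:
        d = {
            "version": self.version,
            "seed": self.seed,
            "n_perm": self.n_perm,
            "tail": self.tail,
            "k": self.k,
            "linkage": self.linkage,
            "input_digests": self.input_digests,
            "n_varieties": self.n_varieties,
            "n_groups": self.n_groups,
            "varieties_dropped": self.varieties_dropped,
            "groups_dropped": self.groups_dropped,
            "results": {m: r.to_dict() for m, r in self.results.items()},
        }
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _digest_inputs(
    wordlists: Sequence[Wordlist], group_map: GroupMap, traits: TraitTable
) -> dict[str, str]:
    def sha(text: str) -> str:
        return hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]

    wl = "\n".join(
        f"{w.variety_id}\t{c}\t{f}\t{k or ''}"
        for w in sorted(wordlists, key=lambda w: w.variety_id)
        for c in sorted(w.entries)
        for f, k in w.entries[c]
    )
    gm = "\n".join(f"{v}\t{g}" for v, g in sorted(group_map.items()))
    tt = "\n".join(f"{g}\t{traits[g]!r}" for g in sorted(traits))
    return {"wordlists": sha(wl), "group_map": sha(gm), "traits": sha(tt)}


def run_analysis(
    wordlists: Sequence[Wordlist],
    group_map: GroupMap,
    traits: TraitTable,
    measures: Sequence[str] = ("cognate",),
    n_perm: int = 10_000,
    tail: str = "greater",
    k: int = 4,
    seed: int = 0,
    linkage: str = "average",
    outdir: str | Path | None = None,
) -> RunReport:
    """Run the full analysis for one or more lexical measures.

    Varieties without a group and groups missing from either the lexical or
    the trait side are dropped (complete-case analysis) and listed in the
    report.  Deterministic given ``seed``.
    """
    for m in measures:
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r}; choose from {MEASURES}")
    wordlists = list(wordlists)
    retained = [w for w in wordlists if w.variety_id in group_map]
    varieties_dropped = sorted(
        w.variety_id for w in wordlists if w.variety_id not in group_map
    )
    if varieties_dropped:
        logger.warning("varieties without group mapping dropped: %s", varieties_dropped)
    # complete-case on groups: keep varieties whose group has a trait value
    lex_groups = {group_map[w.variety_id] for w in retained}
    groups_dropped = sorted(
        (lex_groups - set(traits)) | (set(traits) - lex_groups)
    )
    if groups_dropped:
        logger.warning("groups without complete data dropped: %s", groups_dropped)
    retained = [w for w in retained if group_map[w.variety_id] in traits]
    if len(retained) < 2:
        raise ValidationError("fewer than 2 varieties with complete data")

    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    results: dict[str, MeasureResult] = {}
    n_groups = None
    for measure in measures:
        try:
            vmat = pairwise_matrix(retained, measure)
        except Exception as exc:
            raise StageError("distances", exc) from exc
        try:
            gmat = group_distance_matrix(vmat, group_map)
            tmat = trait_difference_matrix(traits, list(gmat.ids))
            gmat, tmat = align_matrices(gmat, tmat)
        except Exception as exc:
            raise StageError("aggregation", exc) from exc
        try:
            mres = mantel_test(tmat, gmat, n_perm=n_perm, tail=tail, seed=seed)
        except Exception as exc:
            raise StageError("mantel", exc) from exc
        try:
            tree = upgma(vmat, linkage=linkage)
            branches = top_branches(tree, min(k, len(tree)))
        except Exception as exc:
            raise StageError("clustering", exc) from exc
        clusters = {
            lab: ci + 1 for ci, leafset in enumerate(branches) for lab in leafset
        }
        files: dict[str, str] = {}
        if outdir is not None:
            files["variety_matrix"] = str(outdir / f"{measure}_varieties.tsv")
            files["group_matrix"] = str(outdir / f"{measure}_groups.tsv")
            files["trait_matrix"] = str(outdir / f"{measure}_trait_diff.tsv")
            files["tree"] = str(outdir / f"{measure}_tree.nwk")
            files["clusters"] = str(outdir / f"{measure}_clusters.tsv")
            write_matrix(vmat, files["variety_matrix"])
            write_matrix(gmat, files["group_matrix"])
            write_matrix(tmat, files["trait_matrix"])
            Path(files["tree"]).write_text(tree.to_newick() + "\n", encoding="utf-8")
            with open(files["clusters"], "w", encoding="utf-8") as fh:
                fh.write("variety\tcluster\n")
                for lab in tree.leaf_labels:
                    fh.write(f"{lab}\t{clusters[lab]}\n")
        results[measure] = MeasureResult(
            measure=measure,
            mantel=mres,
            clusters=clusters,
            tree_newick=tree.to_newick(),
            files=files,
        )
        n_groups = len(gmat.ids)

    report = RunReport(
        version=__version__,
        seed=seed,
        n_perm=n_perm,
        tail=tail,
        k=k,
        linkage=linkage,
        input_digests=_digest_inputs(wordlists, group_map, traits),
        n_varieties=len(retained),
        n_groups=n_groups,
        varieties_dropped=varieties_dropped,
        groups_dropped=groups_dropped,
        results=results,
    )
    if outdir is not None:
        report.to_json(outdir / "report.json")
    return report
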