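"""End-to-end pipeline: simulate/quantify -> cluster -> predict (-> lda, recurrence).

A :class:`PipelineConfig` gathers every stage's options; :func:`run_pipeline`
executes the stages in order, writes each intermediate as a commented TSV and
finishes with a ``manifest.json`` recording the package version, seed, config
hash and every output file, so a run is reproducible and restartable from any
intermediate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from cladecall import __version__
from cladecall import io
from cladecall.cluster import HierarchicalClades
from cladecall.errors import CladecallError, ConfigurationError
from cladecall.lda import LinearDiscriminant, separation_report
from cladecall.predict import label_clades, predict, predict_refined
from cladecall.qpcr import build_matrix
from cladecall.recurrence import RecurrenceTest
from cladecall.signatures import DEFAULT_PANEL, REFERENCE_GENE, default_signatures
from cladecall.simulate import CohortConfig, generate_cohort


@dataclass
class PipelineConfig:
    """Everything needed for one end-to-end run."""

    out_dir: str = "cladecall_out"
    seed: int = 0
    # inputs: either a Ct table on disk, or simulate=True
    ct_table: str | None = None
    labels_table: str | None = None
    simulate: bool = False
    ancestor: str = "ancestor"
    panel: Sequence[str] = DEFAULT_PANEL
    reference_gene: str = REFERENCE_GENE
    efficiencies: Mapping[str, float] | None = None
    error_mode: str = "bio_sem"
    # clustering
    metric: str = "euclidean"
    k: int | None = None
    k_max: int = 10
    # prediction
    refine: bool = True
    # optional stages
    run_lda: bool = False
    ploidy_table: str | None = None
    mutations_table: str | None = None
    gene_lengths_table: str | None = None
    target_length: int | None = None
    recurrence_null: str = "per_mutation"

    def to_mapping(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashed = {k: v for k, v in config.to_mapping().items() if k != "out_dir"}
    chash = io.config_hash(hashed)
    meta = {"seed": config.seed, "config": chash}
    outputs: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        io.write_table(df, path, meta, index=index)
        outputs[name] = str(path)

    # --- stage: input / simulate -----------------------------------------
    labels = None
    truth = None
    try:
        if config.simulate:
            cohort = CohortConfig(seed=config.seed)
            ct, truth = generate_cohort(cohort, default_signatures())
            emit("ct.tsv", ct)
            emit("truth.tsv", truth)
            labels = truth.set_index("clone")["driver"]
        else:
            if config.ct_table is None:
                raise ConfigurationError("need either a Ct table or simulate=True")
            ct = io.read_table(config.ct_table)
            if config.labels_table:
                lab = io.read_table(config.labels_table)
                lab["clone"] = lab["clone"].astype(str)
                labels = lab.set_index("clone").iloc[:, -1]
    except CladecallError as err:
        raise CladecallError(f"[input] {err}") from err

    # --- stage: quantify ---------------------------------------------------
    try:
        matrix = build_matrix(
            ct,
            ancestor=config.ancestor,
            panel=config.panel,
            reference_gene=config.reference_gene,
            efficiencies=config.efficiencies,
            mode=config.error_mode,
        )
        io.write_matrix(matrix, out / "expression", meta)
        outputs["expression.tsv"] = str(out / "expression.tsv")
        outputs["expression.se.tsv"] = str(out / "expression.se.tsv")
    except CladecallError as err:
        raise CladecallError(f"[quantify] {err}") from err

    # --- stage: cluster ----------------------------------------------------
    try:
        results = HierarchicalClades(matrix, metric=config.metric).fit(
            k=config.k, k_max=config.k_max
        )
        emit(
            "clades.tsv",
            results.assignment.rename_axis("clone").reset_index(),
        )
        emit("clade_trace.tsv", results.trace)
        newick = out / "dendrogram.nwk"
        newick.write_text(results.to_newick() + "\n")
        outputs["dendrogram.nwk"] = str(newick)
    except CladecallError as err:
        raise CladecallError(f"[cluster] {err}") from err

    # --- stage: predict ----------------------------------------------------
    if labels is not None:
        try:
            unlabeled = [c for c in matrix.clones if c not in labels.index]
            targets = unlabeled if unlabeled else list(matrix.clones)
            if config.refine:
                preds = predict_refined(results, labels, targets)
            else:
                lmap = label_clades(results.assignment, labels)
                preds = predict(results.assignment, lmap, targets)
            emit("predictions.tsv", preds)
        except CladecallError as err:
            raise CladecallError(f"[predict] {err}") from err

    # --- stage: lda (optional) ----------------------------------------------
    if config.run_lda and labels is not None:
        try:
            grouping = labels.reindex(matrix.clones).dropna()
            res_mut = LinearDiscriminant(
                matrix.log2.loc[grouping.index], grouping
            ).fit()
            emit(
                "lda_scores.tsv",
                res_mut.scores.join(grouping.rename("class")).reset_index(),
            )
            if truth is not None or config.ploidy_table:
                if truth is not None:
                    ploidy = truth.set_index("clone")["ploidy"]
                else:
                    ptab = io.read_table(config.ploidy_table)
                    ptab["clone"] = ptab["clone"].astype(str)
                    ploidy = ptab.set_index("clone")["ploidy"]
                ploidy = ploidy.reindex(grouping.index).dropna()
                res_plo = LinearDiscriminant(
                    matrix.log2.loc[ploidy.index], ploidy
                ).fit()
                report = separation_report(res_mut, res_plo)
                (out / "lda_report.json").write_text(
                    json.dumps(_jsonable(report), indent=2)
                )
                outputs["lda_report.json"] = str(out / "lda_report.json")
        except CladecallError as err:
            raise CladecallError(f"[lda] {err}") from err

    # --- stage: recurrence (optional) ----------------------------------------
    if config.mutations_table and config.gene_lengths_table and config.target_length:
        try:
            muts = io.read_table(config.mutations_table)
            lengths = io.read_table(config.gene_lengths_table)
            lengths_map = dict(
                zip(lengths["gene"], lengths["length_bp"].astype(int))
            )
            rec = RecurrenceTest(
                muts, lengths_map, config.target_length, null=config.recurrence_null
            ).fit()
            emit("recurrence.tsv", rec.table)
        except CladecallError as err:
            raise CladecallError(f"[recurrence] {err}") from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "config": _jsonable(config.to_mapping()),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (pd.Series, pd.DataFrame)):
        return None
    if hasattr(obj, "item"):
        return obj.item()
    return obj
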