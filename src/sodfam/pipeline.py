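"""Top-level orchestration: scan -> physchem -> classify -> genome context
-> expression, writing TSV result tables and a structured log.

Outputs are a pure function of (inputs, config, seed); rerunning with the
same bundle and seed reproduces the TSVs byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import domain_scan, expression_stats, genome_context, ligand_classify, physchem
from .io_formats import (
    RunConfig,
    SodfamError,
    read_fasta,
    read_gff3,
    write_tsv,
)

logger = logging.getLogger("sodfam")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the cause."""


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    outdir: Path | None = None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out
        return wrapped
    return deco


def run_pipeline(
    config: RunConfig,
    fasta: str | Path,
    gff3: str | Path | None = None,
    counts: str | Path | None = None,
    design: str | Path | None = None,
    lengths: str | Path | None = None,
    control: str | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage the provided inputs allow.

    ``fasta`` is required (scan/physchem/classify); ``gff3`` enables the
    genome-context stage; ``counts`` + ``design`` + ``lengths`` enable the
    expression stage.  All referenced inputs are checked up front so a
    missing file aborts before any stage runs.
    """
    paths = {"fasta": fasta, "gff3": gff3, "counts": counts, "design": design,
             "lengths": lengths}
    for name, p in paths.items():
        if p is not None and not Path(p).is_file():
            raise SodfamError(f"input {name} not readable: {p}")

    result = PipelineResult()
    records = read_fasta(fasta)

    @_stage("scan")
    def do_scan():
        archs, hits = domain_scan.scan_proteome(
            records, threshold=config.evalue_threshold,
            min_protein_len=config.min_protein_len,
        )
        return archs, hits

    archs, hits = do_scan()
    result.tables["candidates"] = domain_scan.hits_table(archs, hits).sort_values(
        ["protein_id", "start"], kind="stable"
    ).reset_index(drop=True)

    cand = domain_scan.candidates(archs)
    cand_ids = {a.protein_id for a in cand}

    @_stage("physchem")
    def do_physchem():
        subset = [r for r in records if r.id in cand_ids]
        return physchem.physchem_table(subset).sort_values("protein_id", kind="stable")

    result.tables["physchem"] = do_physchem().reset_index(drop=True)

    @_stage("classify")
    def do_classify():
        calls, profiles = ligand_classify.classify_proteins(records, archs, hits)
        return ligand_classify.classification_table(calls, profiles)

    result.tables["classification"] = do_classify().sort_values(
        ["protein_id", "domain_index"], kind="stable"
    ).reset_index(drop=True)

    if gff3 is not None:
        @_stage("context")
        def do_context():
            loci = read_gff3(gff3)
            cand_records = [r for r in records if r.id in cand_ids]
            pairs = genome_context.duplicate_pairs(cand_records, loci, config)
            arrays = genome_context.tandem_arrays(pairs, loci, config)
            return (
                genome_context.pairs_table(pairs),
                genome_context.arrays_table(arrays),
            )

        pairs_df, arrays_df = do_context()
        result.tables["duplicate_pairs"] = pairs_df
        result.tables["tandem_arrays"] = arrays_df

    if counts is not None:
        if design is None or lengths is None:
            raise SodfamError("expression stage needs counts, design and lengths together")

        @_stage("express")
        def do_express():
            em = expression_stats.load_expression(counts, design, lengths)
            tpm_df = expression_stats.tpm(em)
            ctrl = control or sorted(em.sample_condition.unique())[0]
            calls = expression_stats.anova_duncan(
                tpm_df, em.sample_condition, control=ctrl, alpha=config.anova_alpha
            )
            abundance = tpm_df.round(4)
            abundance.insert(0, "gene_id", abundance.index)
            return abundance.reset_index(drop=True), expression_stats.calls_table(calls)

        tpm_df, calls_df = do_express()
        result.tables["tpm"] = tpm_df
        result.tables["response_calls"] = calls_df

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in result.tables.items():
            write_tsv(df, outdir / f"{name}.tsv")
        with open(outdir / "run_log.txt", "w") as fh:
            fh.write(f"config: {config}\n")
            for name, df in result.tables.items():
                fh.write(f"table {name}: {len(df)} rows\n")
        result.outdir = outdir
    return result
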