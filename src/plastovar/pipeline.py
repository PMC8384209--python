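"""The end-to-end `compare` pipeline: structure -> junctions ->
inversions -> regions -> alignment -> variability -> ranking -> class
summary, with stable TSV outputs."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .align import align_group, pairwise_identity
from .config import CompareConfig, effective_config
from .io import Plastome, read_genbank
from .regions import extract_regions, group_homologous
from .stats import (class_summary, concatenate_alignments, rank_regions,
                    variability_stats)
from .structure import (detect_quadripartite, detect_gene_order_inversions,
                        gc_report, gene_census, intron_census,
                        junction_report)

log = logging.getLogger("plastovar")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")


def run_compare(paths: list[str | Path], cfg: CompareConfig,
                out_dir: str | Path,
                plastomes: list[Plastome] | None = None) -> dict:
    """Run the full comparative pipeline over >=2 annotated plastomes and
    write the report bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if plastomes is None:
        try:
            plastomes = [read_genbank(p) for p in paths]
        except Exception as e:
            raise StageError("read", str(e)) from e
    if len(plastomes) < 2:
        raise StageError("read", "need at least 2 annotated plastomes")

    # --- structure (Table-3 analog) -------------------------------------
    try:
        structures = {p.id: detect_quadripartite(
            p, min_ir=cfg.min_ir, max_mismatch_frac=cfg.max_mismatch_frac)
            for p in plastomes}
    except Exception as e:
        raise StageError("structure", str(e)) from e
    rows = []
    for p in plastomes:
        q = structures[p.id]
        gc = gc_report(p, q)
        census = gene_census(p, q)
        rows.append({"species": p.id, "plastome_bp": len(p),
                     "lsc_bp": q.lsc_length, "ir_bp": q.ir_length,
                     "ssc_bp": q.ssc_length, "gc_pct": gc.overall_pct,
                     "unique_genes": census["unique_genes"]})
    _tsv(pd.DataFrame(rows), out / "structure.tsv")

    # --- junction geometry (Fig-2 analog) --------------------------------
    try:
        jrows = []
        for p in plastomes:
            rep = junction_report(p, structures[p.id])
            for e in rep.entries:
                jrows.append({"species": p.id, "junction": e.junction,
                              "gene": e.gene, "side": e.side,
                              "distance_bp": e.distance,
                              "spans": int(e.spans)})
    except Exception as e:
        raise StageError("junctions", str(e)) from e
    _tsv(pd.DataFrame(jrows), out / "junctions.tsv")

    # --- gene-order inversions vs the reference (Fig-1 analog) -----------
    ref = plastomes[0] if cfg.reference is None else next(
        p for p in plastomes if p.id == cfg.reference)
    try:
        irows = []
        for p in plastomes:
            if p.id == ref.id:
                continue
            for blk in detect_gene_order_inversions(ref, p):
                irows.append({"reference": ref.id, "query": p.id,
                              "genes": ",".join(blk.genes),
                              "span_ref_bp": blk.span_a,
                              "span_query_bp": blk.span_b})
    except Exception as e:
        raise StageError("inversions", str(e)) from e
    _tsv(pd.DataFrame(irows, columns=["reference", "query", "genes",
                                      "span_ref_bp", "span_query_bp"]),
         out / "inversions.tsv")

    # --- regions, alignment, variability ---------------------------------
    try:
        regions_by_taxon = {p.id: extract_regions(
            p, structures[p.id], drop_ir=cfg.drop_ir) for p in plastomes}
        groups = group_homologous(regions_by_taxon, reference=ref.id)
    except Exception as e:
        raise StageError("regions", str(e)) from e

    try:
        alignments = []
        for g in groups:
            if not g.complete or len(g.members) < 2:
                continue
            aln = align_group(
                {t: r.sequence for t, r in g.members.items()},
                match=cfg.match, mismatch=cfg.mismatch,
                gap_open=cfg.gap_open, gap_extend=cfg.gap_extend,
                region_name=g.name, region_class=g.region_class)
            alignments.append(aln)
    except Exception as e:
        raise StageError("align", str(e)) from e

    try:
        stats = [variability_stats(a) for a in alignments]
        analyzed = [s for s in stats
                    if s.region_class in ("CDS", "IGS", "intron")]
        vdf = pd.DataFrame([{
            "region": s.region_name, "class": s.region_class,
            "n_sites": s.columns.n_sites,
            "invariable": s.columns.n_invariable, "pis": s.columns.n_pis,
            "subs": s.columns.n_subs,
            "indel_events": s.columns.n_indel_events,
            "sv_pct": round(s.sv_pct, 2), "pis_pct": round(s.pis_pct, 2)}
            for s in analyzed])
        _tsv(vdf, out / "variability.tsv")
        for metric in ("sv", "pis"):
            top = rank_regions(analyzed, metric=metric, top_n=cfg.top_n)
            _tsv(pd.DataFrame([{
                "rank": i + 1, "region": s.region_name,
                "class": s.region_class, "sv_pct": round(s.sv_pct, 2),
                "pis_pct": round(s.pis_pct, 2)} for i, s in enumerate(top)]),
                out / f"top{cfg.top_n}_{metric}.tsv")
        summ = class_summary(analyzed)
        _tsv(pd.DataFrame([{
            "scope": c.scope, "mutation_pct": round(c.mutation_pct, 2),
            "indel_pct": round(c.indel_pct, 2),
            "ratio": ("inf" if c.ratio == float("inf")
                      else round(c.ratio, 2))} for c in summ]),
            out / "class_summary.tsv")
        concat = concatenate_alignments(alignments)
        identity = pairwise_identity(concat)
    except Exception as e:
        raise StageError("variability", str(e)) from e

    with open(out / "run.log", "w", encoding="utf-8") as fh:
        fh.write(f"plastovar {__version__}\n")
        fh.write(f"inputs: {[str(x) for x in paths] or [p.id for p in plastomes]}\n")
        fh.write(f"config: {effective_config(cfg)}\n")
        fh.write(f"taxa: {[p.id for p in plastomes]}\n")
        fh.write(f"mean pairwise identity (concatenated regions): "
                 f"{identity:.1f}%\n")
    return {"structures": structures, "groups": groups,
            "alignments": alignments, "stats": analyzed,
            "identity": identity}
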