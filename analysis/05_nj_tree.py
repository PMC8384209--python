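#!/usr/bin/env python
"""Build an NJ tree from the concatenated top-10 SV% regions of the
compare run and report the Robinson-Foulds distance to the generating
topology.  Writes results/nj_top10_sv.nwk."""

import sys
from pathlib import Path

import dendropy

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SIM_DIR, STUDY_SEED

from plastovar.align import align_group
from plastovar.io import AlignmentMatrix
from plastovar.regions import extract_regions, group_homologous
from plastovar.simulate import SimulationConfig, evolve_on_tree, \
    simulate_ancestor
from plastovar.stats import nj_tree, rank_regions, variability_stats
from plastovar.structure import detect_quadripartite


def main():
    cfg = SimulationConfig(seed=STUDY_SEED)
    _, segs = simulate_ancestor(cfg)
    tips, _ = evolve_on_tree(segs, cfg)

    by_taxon = {t: extract_regions(p, detect_quadripartite(p))
                for t, p in tips.items()}
    alns = []
    for g in group_homologous(by_taxon):
        if not g.complete:
            continue
        seqs = {t: r.sequence for t, r in g.members.items()}
        if len(set(seqs.values())) == 1:
            alns.append(AlignmentMatrix(g.name, g.region_class,
                                        list(seqs), list(seqs.values())))
        else:
            alns.append(align_group(seqs, region_name=g.name,
                                    region_class=g.region_class))
    stats = [variability_stats(a) for a in alns
             if a.region_class in ("CDS", "IGS", "intron")]
    top = {s.region_name for s in rank_regions(stats, metric="sv",
                                               top_n=10)}
    newick = nj_tree([a for a in alns if a.region_name in top])
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "nj_top10_sv.nwk").write_text(newick + "\n")

    tns = dendropy.TaxonNamespace()
    got = dendropy.Tree.get(data=newick, schema="newick",
                            taxon_namespace=tns,
                            preserve_underscores=True)
    want = dendropy.Tree.get(data=cfg.tree, schema="newick",
                             taxon_namespace=tns,
                             preserve_underscores=True)
    got.encode_bipartitions()
    want.encode_bipartitions()
    rf = dendropy.calculate.treecompare.symmetric_difference(got, want)
    print(f"top-10 SV regions: {sorted(top)}")
    print(f"NJ vs generating topology: RF = {rf}")


if __name__ == "__main__":
    main()
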