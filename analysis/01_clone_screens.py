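#!/usr/bin/env python
"""Genome-wide screen clone attribution.

Attributes resistant clones from the two packaged clone tables (mouse ES
talazoparib screen; SUM149 talazoparib screen) to causal genes by the
multiple-distinct-designs rule, infers sister clones from shared passenger
guides, and writes the attribution report.
"""

import json
from pathlib import Path

from tagmute.clone_attribution import (
    attribute_hits,
    infer_clonality,
    load_mouse_es_clone_fixture,
    load_sum149_colony_fixture,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    clones = load_mouse_es_clone_fixture()
    res = attribute_hits(clones)
    groups, candidates = infer_clonality(clones)

    print("== mouse ES genome-wide screen ==")
    print(f"clones analysed:          {len(clones)}")
    print(f"multi-design hit genes:   {sorted(res.multi_design_genes)}")
    print(f"clones attributed:        {res.clone_counts_by_cause}")
    print(f"high-confidence sisters:  {[sorted(g) for g in groups]}")
    print(f"candidate links:          {candidates}")

    rows = load_sum149_colony_fixture()
    by_gene: dict[str, int] = {}
    for designs, count in rows:
        for d in designs:
            gene = d.split("_ex")[0]
            by_gene[gene] = by_gene.get(gene, 0) + count
    ex16 = sum(c for designs, c in rows if "PARP1_ex16" in designs)
    print("\n== SUM149 genome-wide screen ==")
    print(f"colonies:                 {sum(c for _, c in rows)}")
    print(f"colonies per gene:        {by_gene}")
    print(f"PARP1 exon-16 colonies:   {ex16}")

    payload = {
        "mouse_es": {
            "n_clones": len(clones),
            "multi_design_genes": sorted(res.multi_design_genes),
            "clone_counts_by_cause": res.clone_counts_by_cause,
            "high_confidence_groups": [sorted(g) for g in groups],
            "candidate_links": [list(p) for p in candidates],
        },
        "sum149": {"colonies_per_gene": by_gene, "parp1_ex16_colonies": ex16},
    }
    (RESULTS / "clone_attribution.json").write_text(json.dumps(payload, indent=2) + "\n")
    with open(RESULTS / "clone_annotations.tsv", "w") as fh:
        fh.write("clone_id\tlikely_cause\tclonal_with\tsgrnas\n")
        for c in res.clones:
            fh.write(
                f"{c.clone_id}\t{c.likely_cause or ''}\t{';'.join(sorted(c.clonal_with))}\t{';'.join(sorted(c.sgrnas))}\n"
            )
    print(f"\nwrote {RESULTS / 'clone_attribution.json'} and clone_annotations.tsv")


if __name__ == "__main__":
    main()
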