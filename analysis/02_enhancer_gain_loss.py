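"""Map the gain and losses of each regulatory element on the mammal tree.

Dollo parsimony on the packaged 139-species topology: each element is
gained once (the enhancer, PRR and CpG island on the stem eutherian
branch) and subsequently lost on a minimal set of branches. Uses the
curated matrix view, in which the two-toed sloth's enhancer cell is
treated as missing data (its assembly lacks the locus entirely).
"""

from pathlib import Path

from regelscreen.phylo_events import (
    SpeciesTree,
    annotate_events_newick,
    curated_species_matrix,
    dollo_losses,
    write_gainloss_tsv,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix, _meta = curated_species_matrix()
    tree = SpeciesTree.packaged_mammal_tree()
    OUT.mkdir(exist_ok=True)
    maps = []
    for el in ("enhancer", "prr", "cpg_island"):
        gl = dollo_losses(tree, matrix, el)
        maps.append(gl)
        print(
            f"{el}: gained on {gl.gain_branch}, "
            f"{gl.n_independent_losses} independent losses "
            f"({', '.join(sorted(gl.loss_branches)) or 'none'})"
        )
    write_gainloss_tsv(maps, OUT / "gainloss.tsv")
    (OUT / "enhancer_events.nwk").write_text(
        annotate_events_newick(tree, maps[0])
    )
    print(f"wrote {OUT / 'gainloss.tsv'} and {OUT / 'enhancer_events.nwk'}")


if __name__ == "__main__":
    main()
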