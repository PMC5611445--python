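"""Tally element presence/coverage in the packaged 139-species table.

Reproduces the cohort bookkeeping of the comparative survey: how many
eutherians carry the enhancer, the putative regulatory region (PRR) and
the CpG island, and how many have sequence coverage to judge.
"""

from pathlib import Path

from regelscreen.phylo_events import packaged_species_matrix
from regelscreen.pipeline import write_tallies_tsv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix, meta = packaged_species_matrix()
    OUT.mkdir(exist_ok=True)
    write_tallies_tsv(matrix, meta, OUT / "table_tallies.tsv",
                      header="# packaged species table tallies\n")
    n_eu = sum(1 for m in meta if m.is_eutherian)
    print(f"{len(meta)} species ({n_eu} eutherians)")
    from regelscreen.phylo_events import count_matrix_tallies

    for el in ("enhancer", "prr", "cpg_island"):
        n_p, n_c, _ = count_matrix_tallies(matrix, meta, el,
                                           eutherian_only=True)
        print(f"  {el}: present in {n_p} of {n_c} eutherians with coverage")
    print(f"wrote {OUT / 'table_tallies.tsv'}")


if __name__ == "__main__":
    main()
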