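"""Generate the synthetic study datasets.

Emulates the raw measurements behind the published species-level summaries:
metaphase-plate chromosome arm lengths for both taxa (10 plates for
*T. scardica*, 36 for *T. undulatifolia*), the 140-individual five-population
trait matrix, and 30 seeds per species. Writes the CSVs every later stage
reads.
"""

from pathlib import Path

from karyodelim import datasets, io_tables
from karyodelim import synthetic_data as synth

SEED = 20240517
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    plate_records = []
    for i, sp in enumerate((datasets.SCARDICA, datasets.UNDULATIFOLIA)):
        spec = synth.default_plate_spec(sp, n_plates=datasets.KARYO_N_PLATES[sp])
        plate_records += synth.simulate_plates(spec, seed=SEED + i)
    io_tables.write_chromosome_table(plate_records, OUT / "chromosome_plates.csv")
    print(f"wrote {len(plate_records)} chromosome records "
          f"({datasets.KARYO_N_PLATES} plates) -> {OUT/'chromosome_plates.csv'}")

    tm = synth.simulate_study_traits(seed=SEED)
    io_tables.write_trait_matrix(tm, OUT / "trait_matrix.csv")
    print(f"wrote {len(tm.data)} individuals x {len(tm.traits)} traits "
          f"over {len(tm.n_per_population)} populations -> {OUT/'trait_matrix.csv'}")

    seeds = []
    for i, sp in enumerate((datasets.SCARDICA, datasets.UNDULATIFOLIA)):
        seeds += synth.simulate_seeds(sp, datasets.SEED_N, seed=SEED + 100 + i)
    io_tables.write_seed_table(seeds, OUT / "seed_table.csv")
    print(f"wrote {len(seeds)} seed records -> {OUT/'seed_table.csv'}")


if __name__ == "__main__":
    main()
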