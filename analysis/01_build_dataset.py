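"""Assemble the modelling dataset from the packaged literature table.

Loads the 49 chrysanthemum transformation studies, resolves range cells to
midpoints, expands multi-strain studies to one row per strain, and encodes
the 11-factor design matrix.  Writes the resolved rows and the encoding
metadata (strain codebook + min-max scaling) under results/.
"""

from pathlib import Path

from chrysopt import database

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    records = database.load_database()
    rows = database.resolve_records(records)
    dataset = database.encode(rows)

    database.export_resolved(rows, OUT / "resolved_rows.csv")
    (OUT / "encoding_metadata.json").write_text(dataset.metadata_json())

    print(f"{len(records)} studies -> {len(rows)} resolved rows "
          f"({len(dataset.strain_codebook)} strains)")
    print(f"efficiency range: {dataset.targets.min():.2f}-{dataset.targets.max():.2f}%")
    print(f"wrote {OUT/'resolved_rows.csv'} and {OUT/'encoding_metadata.json'}")


if __name__ == "__main__":
    main()
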