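#!/usr/bin/env python
"""Merge every suite table into one comparison table.

Writes results/comparison_table.csv: one row per model x scenario with the
trimmed von Mises summary and raw/corrected strain energies.
"""

from pathlib import Path

from craniofea.pipeline import merge_reports

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = merge_reports(OUT)
    df.to_csv(OUT / "comparison_table.csv", index=False, float_format="%.12g")
    print(df.to_string(index=False))
    print(f"{len(df)} rows -> {OUT / 'comparison_table.csv'}")


if __name__ == "__main__":
    main()
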