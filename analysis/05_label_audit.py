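#!/usr/bin/env python
"""Audit the commercial labels of the 34-specimen roster.

Compares each specimen's marketed species name with its molecular
assignment under both complex policies: lenient (sale of an accepted
complex sister under the nominal name is not a mislabel) and strict (only
exact canonical matches pass). The two tallies differ precisely on the
T. longispinosum specimen sold as T. indicum. Writes both audits to
results/.
"""
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from spectratype import SynonymyPolicy, misidentification_report  # noqa: E402
from spectratype.fixtures import commercial_truffle_records  # noqa: E402


def main() -> None:
    records = commercial_truffle_records()
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for mode in ("lenient", "strict"):
        report = misidentification_report(records, SynonymyPolicy.default(mode=mode))
        report.to_csv(results / f"label_audit_{mode}.csv", index=False)
        by = report.attrs["by_marketed"]
        print(f"{mode}: {report.attrs['n_misidentified']} of "
              f"{report.attrs['n_total']} specimens misidentified "
              f"({report.attrs['percent']}%)")
        for _, row in by[by["n_misidentified"] > 0].iterrows():
            print(f"  marketed {row['marketed_species']}: "
                  f"{row['n_misidentified']}/{row['n']} ({row['percent']}%)")
    print(f"tables -> {results}/label_audit_*.csv")


if __name__ == "__main__":
    sys.exit(main())
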