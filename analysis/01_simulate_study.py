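#!/usr/bin/env python
"""Simulate the market-survey study set.

34 commercial truffle specimens spanning seven Tuber species (with the
three-lineage Asian black truffle complex sharing half their peaks), each
measured as 2 biological x 3 technical replicates: 204 linear-mode protein
spectra on a 2-20 kDa grid. Spectra (bulky) go to scratch/study/; the
specimen roster and ground truth go to results/.
"""
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from spectratype import io as sio  # noqa: E402
from spectratype import pipeline  # noqa: E402

SEED = 1


def main() -> None:
    study = pipeline.simulate_fixture_study(seed=SEED)
    out = ROOT / "scratch" / "study"
    sio.write_study(study, out)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    sio.write_metadata_csv(study.records, results / "specimen_roster.csv")

    n_species = len({r.assigned_species for r in study.records})
    print(f"simulated {len(study.records)} specimens, {len(study.spectra)} spectra "
          f"({n_species} species), seed {SEED}")
    print(f"spectra -> {out}")
    print(f"roster  -> {results / 'specimen_roster.csv'}")


if __name__ == "__main__":
    sys.exit(main())
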