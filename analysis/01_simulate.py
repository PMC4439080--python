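#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the structure of the ancient-cattle dataset: a panel of ancient and
modern samples with planted haplogroup profiles across four temporal cohorts
(plus UTY19 fragments for the males), and a heterochronous serial-coalescent
cohort with known theta.  Writes FASTA alignments and TSV metadata under
results/synthetic/ for the downstream drivers.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "tests"))

from paleocattle.haplogroups import default_ruleset
from paleocattle.seqio import write_alignment, write_metadata
from paleocattle.synthdata import SerialCoalescentConfig, simulate_panel, simulate_serial_coalescent
from tests_helpers_panel import PANEL_REGION, PLAN

SEED = 20150520
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    aln, records, truth = simulate_panel(PLAN, default_ruleset(), PANEL_REGION, seed=SEED)
    write_alignment(aln, OUT / "panel_mt.fasta")
    write_alignment(truth["y_alignment"], OUT / "panel_uty19.fasta")
    write_metadata(records, OUT / "panel_metadata.tsv")
    (OUT / "panel_truth.json").write_text(
        json.dumps({k: v for k, v in truth.items() if k != "y_alignment"}, indent=2)
    )
    print(f"panel: {len(aln)} samples, {aln.n_columns} columns, "
          f"{len(truth['y_haplotype'])} male Y fragments -> {OUT}")

    cfg = SerialCoalescentConfig(
        n=20, ages=tuple(float(a) for a in range(0, 20_000, 1000)),
        Ne=1000.0, generation_length=5.0, mu=2.5e-6, L=500, seed=SEED,
    )
    caln, crecords, ctruth = simulate_serial_coalescent(cfg)
    write_alignment(caln, OUT / "serial_coalescent.fasta")
    write_metadata(crecords, OUT / "serial_coalescent_metadata.tsv")
    (OUT / "serial_coalescent_truth.json").write_text(json.dumps(ctruth, indent=2))
    print(f"serial coalescent: n={cfg.n}, theta={cfg.theta:.2f}, "
          f"{ctruth['n_mutations']} mutations")


if __name__ == "__main__":
    main()
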