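#!/usr/bin/env python
"""Heterochrony bias of nucleotide diversity, and its correction, by simulation.

Replicated serial-coalescent simulations with sample ages spread over 20 kyr
show the inflation of the raw mean pairwise difference K above theta by
approximately mu_per_year x mean pairwise age difference, and that the
corrected pi_hmu removes it.  Writes results/heterochrony_bias.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from paleocattle.diversity import (
    HeterochronyParams, heterochrony_correction, mean_pairwise_age_difference, pairwise_k,
)
from paleocattle.synthdata import SerialCoalescentConfig, simulate_serial_coalescent

SEED = 20150520
REPLICATES = 100
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def run(ages: tuple[float, ...], label: str) -> dict:
    n, L, gen, mu = len(ages), 500, 5.0, 2.5e-6
    ks = []
    for rep in range(REPLICATES):
        cfg = SerialCoalescentConfig(n=n, ages=ages, Ne=1000.0, generation_length=gen,
                                     mu=mu, L=L, seed=SEED + rep)
        aln, _, _ = simulate_serial_coalescent(cfg)
        ks.append(pairwise_k(aln))
    theta = cfg.theta
    dt = mean_pairwise_age_difference(ages) if n > 1 else 0.0
    mu_year = mu / gen
    pi_raw = float(np.mean(ks)) / L
    pi_corr, bias = heterochrony_correction(
        pi_raw, HeterochronyParams(rate=mu_year, ages=ages, rate_unit="per_site_per_year")
    )
    return {
        "scenario": label, "replicates": REPLICATES, "theta": theta,
        "mean_K": round(float(np.mean(ks)), 3),
        "se_K": round(float(np.std(ks, ddof=1) / np.sqrt(REPLICATES)), 3),
        "expected_inflation": round(mu_year * dt * L, 3),
        "pi_raw_x1e3": round(pi_raw * 1e3, 3),
        "pi_hmu_x1e3": round(pi_corr * 1e3, 3),
        "bias_pct": round(bias, 2),
    }


def main() -> None:
    rng = np.random.default_rng(SEED)
    homo = (0.0,) * 20
    hetero = tuple(float(a) for a in rng.uniform(0.0, 20_000.0, size=20))
    df = pd.DataFrame([run(homo, "homochronous"), run(hetero, "heterochronous 0-20 kyr BP")])
    df.to_csv(OUT / "heterochrony_bias.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print("\nraw K inflates by ~ rate x mean age spread; the correction recovers theta/L")


if __name__ == "__main__":
    main()
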