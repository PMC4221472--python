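#!/usr/bin/env python
"""Parameter-recovery sweep over seeded synthetic studies.

Simulates 100 studies at the default generator sizes with a recombinant
whose breakpoints flank the causal position, runs the full pipeline on
each, and counts how often the candidate set and the narrowed interval
contain the planted causal variant (expected: always). Also runs 50
studies with 5% missing genotypes under the strict FAIL policy to show
how missing causal genotypes cost recovery. Output:
results/05_recovery.json.
"""

import json
import tempfile
from pathlib import Path

from rumpmap import MissingPolicy, SyntheticCohortSpec, recovery_test

ROOT = Path(__file__).resolve().parents[1]


def sweep(n_runs: int, missing_rate: float, workdir: Path, base_seed: int):
    recovered = contained = 0
    for i in range(n_runs):
        spec = SyntheticCohortSpec(
            seed=base_seed + i,
            recombinant=(86_450_000, 86_650_000),
            n_in_interval=2,
            missing_rate=missing_rate,
        )
        rep = recovery_test(spec, workdir / f"r{missing_rate}_{i}",
                            MissingPolicy.FAIL)
        recovered += rep.causal_recovered
        contained += bool(rep.interval_contains_causal)
    return recovered, contained


def main() -> None:
    with tempfile.TemporaryDirectory() as tmp:
        workdir = Path(tmp)
        rec, cont = sweep(100, 0.0, workdir, base_seed=0)
        rec_miss, cont_miss = sweep(50, 0.05, workdir, base_seed=1000)
    payload = {
        "complete_genotypes": {
            "n_runs": 100,
            "causal_recovered": rec,
            "interval_contains_causal": cont,
        },
        "missing_rate_0.05_policy_fail": {
            "n_runs": 50,
            "causal_recovered": rec_miss,
            "interval_contains_causal": cont_miss,
        },
    }
    out = ROOT / "results" / "05_recovery.json"
    out.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"complete genotypes: causal recovered in {rec}/100 runs, "
          f"interval contains causal in {cont}/100")
    print(f"5% missing genotypes, FAIL policy: recovered in "
          f"{rec_miss}/50 runs (a masked causal genotype is fatal), "
          f"interval contains causal in {cont_miss}/50")
    print(f"results -> {out}")


if __name__ == "__main__":
    main()
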