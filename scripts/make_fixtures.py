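"""Regenerate the committed test fixtures (synthetic; deterministic seeds).

Run from the repository root:  python scripts/make_fixtures.py
"""

import json
from pathlib import Path

from gmediate import simulate

FIXTURES = Path(__file__).resolve().parent.parent / "tests" / "fixtures"

N40_SEED = 40404
TRUTH_SEED = 5
TRUTH_ORACLE_N = 4_000_000


def main() -> None:
    FIXTURES.mkdir(parents=True, exist_ok=True)

    # small synthetic cohort with raw questionnaire columns, for
    # hand-checkable derivation round-trips
    cfg = simulate.study_config(40)
    derived = simulate.generate(cfg, seed=N40_SEED)
    raw = simulate.to_raw_responses(derived, seed=N40_SEED)
    raw.to_csv(FIXTURES / "cohort_n40_raw.csv", index=False)
    derived.to_csv(FIXTURES / "cohort_n40_derived.csv", index=False)

    # ground truth of the default parameter-recovery process
    rcfg = simulate.recovery_config()
    truth = simulate.true_effects(rcfg, oracle_n=TRUTH_ORACLE_N,
                                  seed=TRUTH_SEED)
    payload = {
        "config": rcfg.to_dict(),
        "truth": truth.to_dict(),
        "oracle_seed": TRUTH_SEED,
    }
    (FIXTURES / "recovery_truth.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print("fixtures written to", FIXTURES)


if __name__ == "__main__":
    main()
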