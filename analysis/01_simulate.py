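"""Generate the synthetic input set: survey, price observations, fx, reference costs.

Writes everything (plus truth labels) under scratch/synthetic_inputs/, the
working area the later analysis steps read from. Run first.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from basketcost.pipeline import RunConfig, _simulate_inputs  # noqa: E402

SEED = 1
OUT = ROOT / "scratch" / "synthetic_inputs"


def main() -> None:
    cfg = RunConfig(out_dir=str(OUT), seed=SEED)
    paths = _simulate_inputs(cfg, OUT)
    print(f"seed {SEED}; wrote synthetic inputs:")
    for name, path in paths.items():
        print(f"  {name}: {path}")
    print(f"  truth labels: {OUT / 'truth'}")


if __name__ == "__main__":
    main()
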