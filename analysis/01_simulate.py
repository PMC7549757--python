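#!/usr/bin/env python
"""Generate the benchmark facility pattern the later steps analyze.

Draws a CMS-like synthetic facility table — seven provider categories at
about 1/20 of the national censuses, urban clustering, and planted
attraction of IRF and LTCH points toward acute care hospitals — and writes
it in the S1 dialect to results/synthetic_facilities.csv.

If the real supplementary facility table is available, place it at
data/s1_facilities.txt and the later steps will analyze it instead.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from cloq.synthetic import cms_like_config, generate_pattern, write_pattern

SEED = 20

out_dir = ROOT / "results"
out_dir.mkdir(exist_ok=True)

data = generate_pattern(cms_like_config(seed=SEED))
table = write_pattern(data, out_dir / "synthetic_facilities.csv", state="IA")

print(f"wrote {data.n} facilities to {out_dir / 'synthetic_facilities.csv'}")
print("census by category:")
for cat, n in sorted(data.census().items()):
    print(f"  {cat:>10}: {n}")
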