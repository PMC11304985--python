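"""One-command end-to-end demo: generate -> decode -> cluster MCS ->
behavior scans -> connectivity -> report, all from one master seed.

Equivalent to ``seqrec demo --seed 42 --out results/demo``.
"""

import json
from pathlib import Path

from seqrec.pipeline import RunConfig, run_pipeline


def main() -> None:
    cfg = RunConfig(seed=42, n_participants=10, decode_reps=5,
                    decode_decim=16)
    stats = run_pipeline(cfg, Path("results/demo"))
    print(json.dumps(
        {k: stats[k] for k in ("decoding", "cluster_mcs", "connectivity")},
        indent=1, default=str))
    print("report written to results/demo/report.md")


if __name__ == "__main__":
    main()
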