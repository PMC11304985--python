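"""Generate the synthetic study inputs and write them to results/simulated/.

Produces the three kinds of data every later step consumes: 80 five-tone
melodies (40 memorized / 40 novel), one participant's sensor epochs with an
injected memorized-vs-novel difference, and 90-parcel task + baseline time
series with shared-envelope hubs.  The injected structure is stored next to
the data as ground truth.
"""

import json
from pathlib import Path

from seqrec import io, synth
from seqrec.pipeline import DEFAULT_HUB_PARCELS, default_effect_sites

OUT = Path("results/simulated")
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    melodies = synth.generate_melodies(n_per_category=40, seed=SEED)
    (OUT / "melodies.json").write_text(synth.melodies_to_json(melodies))
    print(f"melodies: {len(melodies)} excerpts, "
          f"{melodies[0].duration_ms:.0f} ms each "
          f"({melodies[0].tone_rate_hz:.0f} Hz tone rate)")

    gt = synth.GroundTruth(
        effect_sites=default_effect_sites(10),
        effect_window=(0.55, 1.18),
        effect_amplitude=25.0,
        hub_parcels=DEFAULT_HUB_PARCELS,
        hub_band=(2.0, 8.0),
        rng_seed=SEED,
    )
    (OUT / "ground_truth.json").write_text(json.dumps(gt.to_dict(), indent=1))

    epochs = synth.generate_epochs(ground_truth=gt, seed=SEED)
    io.save_epochs(epochs, OUT / "epochs_p00")
    print(f"epochs: {epochs.data.shape} (trials x channels x samples), "
          f"{epochs.trials['correct'].sum()} correct trials")

    task, baseline = synth.generate_parcels(ground_truth=gt, seed=SEED)
    io.save_parcels(task, OUT / "parcels_task_p00")
    io.save_parcels(baseline, OUT / "parcels_baseline_p00")
    print(f"parcels: task {task.data.shape}, baseline {baseline.data.shape}; "
          f"hubs {sorted(gt.hub_parcels)} in {gt.hub_band} Hz")


if __name__ == "__main__":
    main()
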