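#!/usr/bin/env python
"""Generate the synthetic cohorts used throughout the analysis and archive
a small example session.

Writes HDF5 session containers for a 12-animal walking cohort and a
22-animal heated cohort (condition-median filter parameters, study-sized
noise), plus a text excerpt of one session's channels, under
``results/sessions/``.
"""

import argparse
from pathlib import Path

from ergpipe.session_io import write_channel_text, write_session
from ergpipe.stimulus import StimulusSpec
from ergpipe.synthetic import (CohortSpec, HEATING_EPOCH_PARAMS,
                               WALKING_EPOCH_PARAMS, WALKING_LATENCY_MS,
                               TemperatureModel, heating_protocol, iter_cohort,
                               latency_from_temperature, walking_protocol)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sessions"))
    ap.add_argument("--n-walking", type=int, default=12)
    ap.add_argument("--n-heating", type=int, default=22)
    args = ap.parse_args()

    model = TemperatureModel()
    cohorts = {
        "walking": CohortSpec(
            n_animals=args.n_walking,
            protocol=walking_protocol(before_s=35, active_s=35, after_s=40),
            seed=args.seed, epoch_params=WALKING_EPOCH_PARAMS,
            latency_medians=WALKING_LATENCY_MS, snr=2.0, artefact_rel_amp=0.05,
            stimulus=StimulusSpec()),
        "heating": CohortSpec(
            n_animals=args.n_heating,
            protocol=heating_protocol(before_s=35, active_s=35, after_s=40),
            seed=args.seed + 1, epoch_params=HEATING_EPOCH_PARAMS,
            latency_medians={lbl: latency_from_temperature(T, model)
                             for lbl, T in (("before", 26.9), ("active", 31.9),
                                            ("after", 27.0))},
            snr=2.0, artefact_rel_amp=0.05, stimulus=StimulusSpec()),
    }
    for name, spec in cohorts.items():
        out = args.out / name
        n = 0
        for session in iter_cohort(spec):
            write_session(session, out / f"{session.animal_id}.h5")
            n += 1
        print(f"{name}: wrote {n} sessions to {out}")

    # text excerpt of the first walking session (2 s of each channel)
    excerpt_dir = args.out / "walking_a00_text_excerpt"
    for session in iter_cohort(cohorts["walking"]):
        for name, ts in session.channels.items():
            write_channel_text(ts.crop(0, 2), excerpt_dir / f"{name}.tsv")
        break
    print(f"text excerpt in {excerpt_dir}")


if __name__ == "__main__":
    main()
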