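#!/usr/bin/env python
"""Generate one ground-truthed synthetic conjugation movie.

Samples a field of mating triplets (donor / recipient / donor), scripts
the transfer events from the kinetic model, renders the four channels, and
writes the movie + ground truth: TIFF stacks under scratch/movie/ (binary,
regeneratable) and the truth tables under results/.
"""

from pathlib import Path

from conjview import SimScenario, render_movie, sample_population
from conjview.io import write_labels, write_movie

ROOT = Path(__file__).resolve().parents[1]
SEED = 42


def main() -> None:
    scenario = SimScenario(n_pairs=10, n_extra_donors=1, n_extra_recipients=1, n_frames=60)
    cells, events = sample_population(scenario, SEED)
    rr = render_movie(cells, events, None, scenario, SEED + 1)

    movie_dir = ROOT / "scratch" / "movie"
    write_movie(rr.movie, movie_dir)
    write_labels(rr.labels, movie_dir / "truth_labels.tif")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    rr.cells_truth.to_csv(out / "truth_cells.csv", index=False)
    rr.events_truth.to_csv(out / "truth_events.csv", index=False)
    rr.foci_truth.to_csv(out / "truth_foci.csv", index=False)
    scenario.to_yaml(out / "scenario.yaml")

    n_conv = rr.events_truth.query("acquisition_index == 1").converted.sum()
    print(f"{len(cells)} cells, {len(events)} scripted transfer events ({n_conv} convert)")
    print(f"movie -> {movie_dir} ; truth tables -> {out}")


if __name__ == "__main__":
    main()
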