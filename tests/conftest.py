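import warnings

import numpy as np
import pytest

from conjview.workflows import FieldResult, recovery_scenario, run_field

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_field() -> FieldResult:
    """One fully processed synthetic field under the default study conditions."""
    scenario = recovery_scenario(n_pairs=10, n_frames=60)
    return run_field(scenario, 123)


def map_roots_to_truth(res: FieldResult) -> dict[int, int]:
    """Lineage-root track id -> ground-truth cell id (frame-0 mask overlap)."""
    lab0 = res.labels[0]
    tl0 = res.truth.labels[0]
    out: dict[int, int] = {}
    for t in res.tracks:
        if t.parent is not None or 0 not in t.frames:
            continue
        m = lab0 == t.frames[0]
        vals, cnts = np.unique(tl0[m][tl0[m] > 0], return_counts=True)
        if len(vals):
            out[t.track_id] = int(vals[cnts.argmax()])
    return out


def truth_class_of(res: FieldResult) -> dict[int, str]:
    """Ground-truth cell id -> expected classification."""
    converted = {e.recipient_id for e in res.truth.events if e.conversion_min is not None}
    out = {}
    for c in res.truth.cells:
        if c.role == "donor":
            out[c.cell_id] = "donor"
        else:
            out[c.cell_id] = "transconjugant" if c.cell_id in converted else "recipient"
    return out
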