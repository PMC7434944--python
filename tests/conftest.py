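import numpy as np
import pytest

from nanorevise.synthetic import Dataset, ErrorProfile, PoreModel, generate_dataset
from nanorevise.types import Event, EventTable, RawSignal


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """20 synthetic reads of 300 bp at the default 15% error rate."""
    return generate_dataset(20, 300, seed=11, ref_length=800)


@pytest.fixture(scope="session")
def methyl_dataset() -> Dataset:
    """Reads over a methylated reference with a visible current shift."""
    pore = PoreModel(methyl_shift=15.0)
    return generate_dataset(12, 300, pore=pore, seed=13, ref_length=800,
                            methyl_density=0.05)


@pytest.fixture(scope="session")
def clean_dataset() -> Dataset:
    """Error-free reads (truth alignments are all matches)."""
    return generate_dataset(10, 250, errors=ErrorProfile.error_free(),
                            seed=17, ref_length=600)


def make_table(moves, lengths, sequence, seed=0, read_id="r0"):
    """Hand-build an event stream with the given move/length pattern."""
    rng = np.random.default_rng(seed)
    events = []
    start = 0
    for mv, ln in zip(moves, lengths):
        seg = rng.normal(90.0, 2.0, size=ln)
        events.append(Event(start=start, length=ln, mean=float(seg.mean()),
                            stdv=float(seg.std()), model_state="ACGTA",
                            move=mv, weight=1.0, p_model_state=0.9,
                            base=sequence[0]))
        start += ln
    total = start
    raw = RawSignal(read_id=read_id,
                    samples=rng.normal(90.0, 2.0, size=total))
    # rebuild event stats from the actual raw samples
    for ev in events:
        seg = raw.samples[ev.start:ev.start + ev.length]
        ev.mean, ev.stdv = float(seg.mean()), float(seg.std())
    table = EventTable(read_id=read_id, events=events, sequence=sequence)
    return raw, table
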