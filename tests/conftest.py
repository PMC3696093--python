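import numpy as np
import pytest

from ctrics import GenomeTable, ScoreParams, WindowedTrack


@pytest.fixture
def genome():
    return GenomeTable({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_track(values_by_chrom, w=200, genome=None, value_kind="raw"):
    values = {c: np.asarray(v) for c, v in values_by_chrom.items()}
    total = int(sum(v.sum() for v in values.values())) if value_kind == "raw" else 0
    if genome is None:
        genome = GenomeTable({c: v.size * w for c, v in values.items()})
    return WindowedTrack(window_size=w, values=values, total_tags=total,
                         value_kind=value_kind, genome=genome)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


@pytest.fixture
def quick_params():
    return ScoreParams(n_boot=20_000, seed=11)
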