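import numpy as np
import pytest

from centroidlex.embeddings import EmbeddingSpace
from centroidlex.synthetic import make_space


@pytest.fixture
def toy_space() -> EmbeddingSpace:
    """Five 2-D words with hand-chosen directions (angles 0..90 degrees)."""
    angles = np.deg2rad([0, 20, 45, 70, 90])
    vecs = np.column_stack([np.cos(angles), np.sin(angles)])
    return EmbeddingSpace(["east", "ene", "ne", "nne", "north"], vecs)


@pytest.fixture
def small_space() -> EmbeddingSpace:
    return make_space(200, 8, seed=11)


@pytest.fixture
def vec_file(tmp_path):
    """A 3-word word2vec-text file (header '3 2')."""
    p = tmp_path / "toy.vec"
    p.write_text("3 2\na 1 0\nb 0 1\nc 1 1\n", encoding="utf-8")
    return p
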