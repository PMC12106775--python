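import numpy as np
import pytest

from cdr3gen import AMINO_ACIDS, Repertoire, SyntheticConfig, generate_cdr3_like


@pytest.fixture
def small_repertoire():
    return Repertoire(["CASF", "CAVR", "CASSLGQAYEQYF"], label="real_tcr")


@pytest.fixture
def cdr3_repertoire():
    return generate_cdr3_like(SyntheticConfig(n=300, seed=42))


@pytest.fixture
def meme_file(tmp_path):
    """Write a MEME minimal-motif file; returns a factory taking row lists."""

    def _write(motifs: dict[str, list[list[float]]], alphabet: str = AMINO_ACIDS):
        lines = ["MEME version 5.5.7", "", f"ALPHABET= {alphabet}", ""]
        for name, rows in motifs.items():
            lines += [f"MOTIF {name}",
                      f"letter-probability matrix: alength= {len(alphabet)} w= {len(rows)}"]
            lines += [" ".join(f"{v:.6f}" for v in row) for row in rows]
            lines.append("")
        path = tmp_path / "motifs.meme"
        path.write_text("\n".join(lines))
        return path

    return _write


def random_sequences(rng: np.random.Generator, n: int, lo: int = 3, hi: int = 25):
    letters = np.array(list(AMINO_ACIDS))
    return ["".join(rng.choice(letters, size=rng.integers(lo, hi + 1)))
            for _ in range(n)]
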