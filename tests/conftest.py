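"""Shared fixtures and hypothesis strategies for the test suite."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings, strategies as st

from emlive import fixtures as fx
from emlive.star_io import LoopTable, StarBlock, StarDocument

# derandomized, bounded profiles so the suite is reproducible and quick
settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# STAR document strategies

_IDENT = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789",
    min_size=1, max_size=12,
)
_LABELS = _IDENT.map(lambda s: "_rln" + s)

# text cells: printable, no newlines, no quote characters (serializer
# quotes everything else that needs it)
_TEXT_CELL = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyz0123456789._/- #@",
    min_size=0, max_size=15,
).filter(lambda s: "\n" not in s)


def _quantized_float(x: float) -> float:
    return fx.quantize(x)


_FLOAT_CELL = st.floats(
    min_value=-1e8, max_value=1e8, allow_nan=False, allow_infinity=False
).map(_quantized_float)

_SCALARS = st.one_of(
    st.integers(min_value=-(10**12), max_value=10**12),
    _FLOAT_CELL,
    _TEXT_CELL,
)


@st.composite
def loop_tables(draw):
    labels = draw(
        st.lists(_LABELS, min_size=1, max_size=5, unique=True)
    )
    n_rows = draw(st.integers(min_value=0, max_value=6))
    rows = [
        tuple(draw(_SCALARS) for _ in labels) for _ in range(n_rows)
    ]
    return LoopTable(labels, rows)


@st.composite
def star_blocks(draw, name: str):
    pair_labels = draw(st.lists(_LABELS, min_size=0, max_size=4, unique=True))
    pairs = {lbl: draw(_SCALARS) for lbl in pair_labels}
    table = draw(st.one_of(st.none(), loop_tables()))
    if not pairs and table is None:
        table = draw(loop_tables())
    return StarBlock(name=name, pairs=pairs, table=table)


@st.composite
def star_documents(draw):
    names = draw(st.lists(_IDENT, min_size=0, max_size=4, unique=True))
    return StarDocument([draw(star_blocks(name)) for name in names])


# ---------------------------------------------------------------------------
# Project fixtures


@pytest.fixture(scope="session")
def mini_project(tmp_path_factory) -> Path:
    """A small synthetic project with images and a 2D classification run."""
    root = tmp_path_factory.mktemp("proj") / "mini"
    spec = fx.FixtureSpec(
        seed=7,
        n_micrographs=5,
        image_size=64,
        pixel_size=1.0,
        run_plan=fx.RunPlan(kind="Class2D", n_classes=3, n_iterations=4),
    )
    fx.make_project(spec, root)
    return root


@pytest.fixture(scope="session")
def metadata_project(tmp_path_factory) -> Path:
    """A metadata-only project (no MRC/profile files), 10 micrographs."""
    root = tmp_path_factory.mktemp("proj_meta") / "meta"
    spec = fx.FixtureSpec(seed=3, n_micrographs=10, write_images=False)
    fx.make_project(spec, root)
    return root


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
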