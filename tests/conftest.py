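import io

import numpy as np
import pytest
from hypothesis import settings

from shortcourse.io import assemble_dataset, parse_expression_file, parse_label_file

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

EXPR_TEXT = (
    "ID\tSymbol\tA1\tA2\tA3\tA4\tB1\tB2\tB3\tB4\n"
    "g1\tGENE1\t1.0\t2.0\t3.0\t4.0\t1.5\t2.5\t3.5\t4.5\n"
    "g2\tGENE2\t5.0\t4.0\t3.0\t2.0\t5.0\t4.0\t\t2.0\n"
    "g3\tGENE3\t0.0\t1.0\t0.0\t1.0\t0.0\t1.0\t0.0\t1.0\n"
)

# two treatments x two replicates, two times per replicate
LABEL_TEXT = (
    "Array\tA1\tA2\tA3\tA4\tB1\tB2\tB3\tB4\n"
    "Treatment\talpha\talpha\talpha\talpha\tcontrol\tcontrol\tcontrol\tcontrol\n"
    "Replicate\t1\t1\t2\t2\t1\t1\t2\t2\n"
    "Time\t0\t24\t0\t24\t0\t24\t0\t24\n"
    "Paired\tyes\tyes\tyes\tyes\tyes\tyes\tyes\tyes\n"
)


@pytest.fixture
def expr_matrix():
    return parse_expression_file(io.StringIO(EXPR_TEXT))


@pytest.fixture
def design():
    return parse_label_file(io.StringIO(LABEL_TEXT))


@pytest.fixture
def dataset(expr_matrix, design):
    return assemble_dataset(expr_matrix, design)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
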