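import random

import pytest

from belhier.sentence_simplify import read_conllu
from belhier.synth_fixtures import GenConfig, generate_corpus

# Hand-checked dependency parse of the simplification example sentence.
# Tokens: Down-regulation of GENE_1 with small interfering RNA (siRNA) in
# pancreatic carcinoma cells resulted in the up-regulation of GENE_2 and
# GENE_3 expression
FIG_SENTENCE = (
    "Down-regulation of GENE_1 with small interfering RNA (siRNA) in "
    "pancreatic carcinoma cells resulted in the up-regulation of GENE_2 "
    "and GENE_3 expression"
)

FIG_CONLLU = """\
# sent_id = fig4
1\tDown-regulation\t_\t_\t_\t_\t13\tnsubj\t_\t_
2\tof\t_\t_\t_\t_\t1\tprep\t_\t_
3\tGENE_1\t_\t_\t_\t_\t2\tpobj\t_\t_
4\twith\t_\t_\t_\t_\t1\tprep\t_\t_
5\tsmall\t_\t_\t_\t_\t7\tamod\t_\t_
6\tinterfering\t_\t_\t_\t_\t7\tamod\t_\t_
7\tRNA\t_\t_\t_\t_\t4\tpobj\t_\t_
8\t(siRNA)\t_\t_\t_\t_\t7\tappos\t_\t_
9\tin\t_\t_\t_\t_\t1\tprep\t_\t_
10\tpancreatic\t_\t_\t_\t_\t12\tamod\t_\t_
11\tcarcinoma\t_\t_\t_\t_\t12\tamod\t_\t_
12\tcells\t_\t_\t_\t_\t9\tpobj\t_\t_
13\tresulted\t_\t_\t_\t_\t0\troot\t_\t_
14\tin\t_\t_\t_\t_\t13\tprep\t_\t_
15\tthe\t_\t_\t_\t_\t16\tdet\t_\t_
16\tup-regulation\t_\t_\t_\t_\t14\tpobj\t_\t_
17\tof\t_\t_\t_\t_\t16\tprep\t_\t_
18\tGENE_2\t_\t_\t_\t_\t21\tnmod\t_\t_
19\tand\t_\t_\t_\t_\t20\tcc\t_\t_
20\tGENE_3\t_\t_\t_\t_\t21\tconj\t_\t_
21\texpression\t_\t_\t_\t_\t17\tpobj\t_\t_
"""


@pytest.fixture(scope="session")
def fig_parse(tmp_path_factory):
    path = tmp_path_factory.mktemp("fig") / "fig4.conllu"
    path.write_text(FIG_CONLLU)
    return read_conllu(path)[0]


@pytest.fixture(scope="session")
def small_corpus():
    """Default-configuration corpus exercising or-trees and distractors."""
    return generate_corpus(GenConfig(n_pairs=120, seed=3))


@pytest.fixture(scope="session")
def low_noise_corpus():
    """Single-statement (L=3) corpus used by alignment/labeling tests."""
    return generate_corpus(GenConfig.low_noise(n_pairs=330, seed=7))


@pytest.fixture()
def rng():
    return random.Random(12345)
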