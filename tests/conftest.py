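import numpy as np
import pytest

import pgksite as pg
from pgksite.windowing import NEGATIVE, POSITIVE, PeptideWindow


@pytest.fixture
def toy_windows():
    """Three 5-mers (zeta=2) used as a hand-countable positive subset."""
    return [
        PeptideWindow("T1", 3, "ARKAR", POSITIVE),
        PeptideWindow("T2", 3, "ARKRA", POSITIVE),
        PeptideWindow("T3", 3, "CRKAR", POSITIVE),
    ]


@pytest.fixture
def toy_dataset(toy_windows):
    """toy_windows as positives plus three background negatives."""
    negatives = [
        PeptideWindow("N1", 3, "GGKGG", NEGATIVE),
        PeptideWindow("N2", 3, "GHKHG", NEGATIVE),
        PeptideWindow("N3", 3, "HGKGH", NEGATIVE),
    ]
    return pg.WindowDataset(windows=toy_windows + negatives, zeta=2)


@pytest.fixture(scope="session")
def small_enriched_dataset():
    """A small enriched dataset shared by the slower end-to-end tests."""
    spec = pg.SyntheticSpec(
        n_proteins=40,
        length_range=(300, 500),
        n_pos_sites=60,
        n_neg_sites=600,
        zeta=5,
        enrichment=pg.motif_enrichment(5, 3.0),
        first_order_coupling=0.15,
        seed=11,
    )
    ds = pg.generate(spec)
    return spec, pg.build_dataset(ds.proteins, ds.annotations, zeta=5)


def brute_force_tables(windows, zeta):
    """Independent nested-loop counter for the coupling tables."""
    from pgksite.windowing import ALPHABET

    n = len(windows)
    conditional = {}
    marginal = {}
    flanks = [w.residues[:zeta] + w.residues[zeta + 1 :] for w in windows]
    for p in range(1, 2 * zeta + 1):
        if p in (zeta, zeta + 1):
            probs = np.zeros(len(ALPHABET))
            for f in flanks:
                probs[ALPHABET.index(f[p - 1])] += 1
            marginal[p] = probs / n if n else probs
        else:
            q = p + 1 if p < zeta else p - 1
            table = np.zeros((len(ALPHABET), len(ALPHABET)))
            for a_i, a in enumerate(ALPHABET):
                for b_i, b in enumerate(ALPHABET):
                    pair = sum(
                        1 for f in flanks if f[p - 1] == a and f[q - 1] == b
                    )
                    cond = sum(1 for f in flanks if f[q - 1] == b)
                    table[a_i, b_i] = pair / cond if cond else 0.0
            conditional[p] = table
    return conditional, marginal


def brute_force_auc(labels, scores):
    """All-pairs concordance count; ties weigh one half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y != 1]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))
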