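import numpy as np
import pytest

from ubiquifold import (
    ChromatinAnnotation,
    EfretTrace,
    caly_like_design,
    simulate_genome,
)


@pytest.fixture
def efret_trace_factory():
    """Build an EfretTrace directly from raw E values (all frames valid)."""

    def make(values, molecule_id="m"):
        values = np.asarray(values, dtype=float)
        return EfretTrace(molecule_id, values, np.ones(values.size, dtype=bool))

    return make


@pytest.fixture
def planted_genome():
    """The standard PR-DUB-mutant planted genome plus its truth record."""
    params = caly_like_design(seed=11)
    annotation, genes, truth = simulate_genome(params)
    return params, annotation, genes, truth


def base_level_agreement(
    truth_annotation: ChromatinAnnotation,
    called_annotation: ChromatinAnnotation,
) -> float:
    """Fraction of bases whose called class matches the planted class."""
    agree = total = 0
    for chrom, length in truth_annotation.genome.items():
        true_lab = np.empty(length, dtype=object)
        call_lab = np.empty(length, dtype=object)
        for d in truth_annotation.domains:
            if d.chrom == chrom:
                true_lab[d.start : d.end] = d.label
        for d in called_annotation.domains:
            if d.chrom == chrom:
                call_lab[d.start : d.end] = d.label
        agree += int(np.sum(true_lab == call_lab))
        total += length
    return agree / total
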