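import numpy as np
import pandas as pd
import pytest

from sexbias.io_formats import CountMatrix, GeneAnnotation, SampleSheet
from sexbias.normalization import NormalizedExpression, normalize
from sexbias.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated dataset: planted sex effects,
    escapees, erosion, gametolog pairs, Y genes."""
    cfg = SimulationConfig(
        n_autosomal=300,
        n_x=60,
        n_y=10,
        n_gametolog_pairs=5,
        n_planted_sexbiased=10,
        erosion_fraction_per_line={"F1": 0.1, "F2": 0.1, "F3": 0.1},
        seed=1,
    )
    cm, truth = simulate(cfg)
    return cm, truth, normalize(cm)


@pytest.fixture
def design_sheet():
    """3+3 lines x 4 timepoints x 3 replicates sample sheet."""
    rows = []
    for sex, prefix in (("XX", "F"), ("XY", "M")):
        for i in (1, 2, 3):
            for tp in ("D0", "D4", "D9", "D37"):
                for rep in (1, 2, 3):
                    rows.append(
                        {
                            "sample_id": f"{prefix}{i}_{tp}_r{rep}",
                            "cell_line": f"{prefix}{i}",
                            "sex": sex,
                            "timepoint": tp,
                            "replicate": rep,
                        }
                    )
    return SampleSheet(pd.DataFrame(rows))


def make_annotation(gene_ids, chromosomes=None, escapee=(), partners=None):
    chromosomes = chromosomes or {g: "1" for g in gene_ids}
    partners = partners or {}
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "symbol": list(gene_ids),
                "chromosome": [chromosomes[g] for g in gene_ids],
                "length_bp": [1000] * len(gene_ids),
                "escapee": [g in set(escapee) for g in gene_ids],
                "gametolog_partner": [partners.get(g) for g in gene_ids],
            }
        )
    )


def make_norm(values: pd.DataFrame, sheet: SampleSheet, annotation=None):
    """Wrap an already-normalized matrix in a NormalizedExpression."""
    ann = annotation or make_annotation(values.index)
    return NormalizedExpression(
        counts=values,
        size_factor=pd.Series(1.0, index=values.columns),
        norm=values,
        samples=sheet,
        genes=ann,
    )
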