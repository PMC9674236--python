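import numpy as np
import pandas as pd

from enteropep.quant_io import QuantTable


def make_table(values: np.ndarray, sequences=None, genotypes=None, clones=None,
               replicates=None, mods=None) -> QuantTable:
    """Small QuantTable builder for unit tests."""
    m, n = values.shape
    sequences = sequences or [f"PEPTIDE{i}A" for i in range(m)]
    genotypes = genotypes or ["WT"] * n
    clones = clones or [f"c{j}" for j in range(n)]
    replicates = replicates or [1] * n
    sample_ids = [f"s{j}" for j in range(n)]
    samples = pd.DataFrame({
        "sample_id": sample_ids, "clone_id": clones, "genotype": genotypes,
        "bmp": ["minus"] * n, "replicate": replicates,
    })
    peptides = pd.DataFrame({
        "sequence": sequences,
        "modifications": mods if mods is not None else [""] * m,
    })
    return QuantTable(peptides=peptides, samples=samples,
                      values=pd.DataFrame(values, columns=sample_ids))
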