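import numpy as np
import pytest

from iclipkit.annotate import Annotation, Gene, Region
from iclipkit.exonsets import ExonRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_exon(exon_id: str, sequence: str, label: str = "", **kw) -> ExonRecord:
    defaults = dict(gene_id=f"g_{exon_id}", chrom="chrT", start=0,
                    end=len(sequence), strand="+", midas_p=0.5,
                    fold_change=1.0)
    defaults.update(kw)
    return ExonRecord(exon_id=exon_id, sequence=sequence,
                      class_label=label, **defaults)


def random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def two_gene_model():
    """Hand-built 2-gene annotation on a 3000-nt chromosome.

    geneA (+): UTR5 100-150, intron 150-350, ORF 350-500, intron 500-700,
               UTR3 700-800
    geneB (-): UTR3 1200-1300, intron 1300-1450, ORF 1450-1600,
               intron 1600-1750, UTR5 1750-1820  (genomic order)
    """
    gene_a = Gene("geneA", "chr1", 100, 800, "+", [
        Region(100, 150, "UTR5"), Region(150, 350, "intron"),
        Region(350, 500, "ORF"), Region(500, 700, "intron"),
        Region(700, 800, "UTR3")])
    gene_b = Gene("geneB", "chr1", 1200, 1820, "-", [
        Region(1200, 1300, "UTR3"), Region(1300, 1450, "intron"),
        Region(1450, 1600, "ORF"), Region(1600, 1750, "intron"),
        Region(1750, 1820, "UTR5")])
    return Annotation([gene_a, gene_b]), {"chr1": 3000}
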