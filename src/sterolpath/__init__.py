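"""In-silico reconstruction of the Schizochytrium mevalonate/sterol pathway.

The package mirrors a genome-mining + chemical-biology study design:

* :mod:`sterolpath.catalog` — the enzyme-activity inventory for the
  terpenoid backbone (MVA / MEP) and sterol sections, plus the sterol
  reaction graph.
* :mod:`sterolpath.align` — affine-gap pairwise protein alignment with
  Karlin–Altschul E-values and alignment-mediated coordinate transfer.
* :mod:`sterolpath.annotate` — ortholog assignment and the two
  sequence-rule classifiers: oxidosqualene-cyclase product specificity
  (residues 381/449/453, human-OSC numbering) and alternative squalene
  epoxidase detection (nine conserved histidines).
* :mod:`sterolpath.pathway` — backbone verdict (MVA vs MEP), sterol-route
  reachability, and in-silico knockouts mirroring inhibitor targets.
* :mod:`sterolpath.quant` — internal-standard quantification (mg/g DCW),
  dose–response effect estimates with paired t-tests, and 2^(−ΔΔCt)
  relative expression.
* :mod:`sterolpath.synth` — synthetic proteomes and experiment tables with
  planted ground truth, used by the analysis scripts and the test suite.
"""

__version__ = "0.1.0"

from importlib import resources


def data_path(*parts: str):
    """Return a traversable path to a bundled data file."""
    p = resources.files("sterolpath") / "data"
    for part in parts:
        p = p / part
    return p
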