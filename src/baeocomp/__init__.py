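"""baeocomp: comparative genomics of multi-strain cyanobacterial gene sets.

Stages: taxonomic contig binning by hit-profile rules, reciprocal-best-hit
homology classification, Nei–Gojobori Ks/Ka estimation with a windowed-Ks
horizontal-transfer screen, Tajima relative rate tests, presence/absence
class analysis, and plasmid-location enrichment — exercised end to end on a
seeded synthetic strain-set generator with full ground truth.
"""

from .binning import BinDecision, ContigHitProfile, classify_contig, congruence_filter
from .divergence import (
    CodonAlignment,
    KsWindowSeries,
    PairwiseDivergence,
    RateTestResult,
    concatenate,
    filter_multiple_of_three,
    mann_whitney,
    ng86,
    tajima_rrt,
    windowed_ks,
)
from .homology import (
    GeneRecord,
    HomologyCall,
    best_hit,
    classify_all,
    classify_rbh,
    summarize_homology,
    union_no_similarity,
)
from .inventory import (
    PresenceMatrix,
    build_matrix,
    class5_presence_frequency,
    class_category_profile,
    strain_absence_frequency,
)
from .pipeline import RunConfig, run_pipeline
from .plasmid import (
    CompartmentCall,
    Contingency2x2,
    FisherResult,
    apply_threshold,
    enrichment_pipeline,
    fisher_exact,
    plasmid_fraction,
)
from .simdata import SimConfig, SimTruth, simulate_strain_set, write_fixture

__version__ = "0.1.0"
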