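"""Headline statistics of the Gironde estuary reference classification.

The per-cell trajectory calls of the published 19-taxon Gironde analysis
are bundled as reference data; the summary stage recomputes the study's
headline counts from them.
"""

import json

from phenomatch import summarize
from phenomatch.datasets import (GROUPS, PRESENCE,
                                 reference_interaction_calls,
                                 reference_overlap_means,
                                 reference_species_calls)

tables = summarize(
    reference_species_calls(), reference_interaction_calls(),
    presence=PRESENCE, groups=GROUPS,
    overlap_period_means=reference_overlap_means())

print(tables.species_table.to_string())
print()
print(json.dumps(tables.stats, indent=2, default=str))
print("\nReading: 55 pairwise period comparisons were possible per "
      "indicator (18 fully present taxa x 3 pairs + 1 taxon absent in the "
      "first regime x 1 pair); 45.3% of the 95 species x indicator cells "
      "changed significantly; 16 of the 46 documented predator-prey "
      "interactions changed their temporal overlap.")
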