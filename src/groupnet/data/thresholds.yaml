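# Default diagnostic thresholds for small intervention groups.
# comparator semantics (applied to the observed value):
#   eq   pass iff observed == value
#   gt   pass iff observed >  value
#   lt   pass iff observed <  value
#   band pass iff lower < observed < upper
# An undefined observation (e.g. reciprocity of an empty network) is
# "cannot evaluate", never a flag.
isolates:        {comparator: eq,   value: 0}
degree:          {comparator: gt,   value: 1}      # per member, total degree
reciprocity:     {comparator: gt,   value: 0.50}   # dyad-based non-null
components:     {comparator: eq,   value: 0}      # excess weak components
density:         {comparator: band, lower: 0.15, upper: 0.50}
centralization:  {comparator: lt,   value: 0.25}   # total-degree variant
transitivity:    {comparator: gt,   value: 0.30}
cohesion:        {comparator: gt,   value: 0.25}   # compactness, want higher
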