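"""Merge a user-supplied reaction to unlock an otherwise infeasible target.

The 1-butanol network ships without a 2-oxovalerate synthesis step, so no
pathway exists.  Merging the chain-elongation addition (the step strain
engineers overexpress for this precursor) makes the published 3-step route
appear.
"""

from retroflux.enumeration import enumerate_pathways
from retroflux.fixtures_oracle import published_fixture
from retroflux.netdb import merge_user_reactions

fx = published_fixture("F-BUOH")
before = enumerate_pathways(fx.db, fx.scope, fx.target)
print(f"before merge: beta* = {before.beta_star} (no pathway)")

merged = merge_user_reactions(fx.db, fx.additions)
after = enumerate_pathways(merged, fx.scope, fx.target)
p = after.found[0][0]
print(f"after merge:  beta* = {after.beta_star}")
print("  " + " -> ".join(p.reactions))
# The merged precursor step plus decarboxylase and dehydrogenase give the
# 3-step 2-ketobutyrate -> 2-oxovalerate -> butanal -> butanol route.
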