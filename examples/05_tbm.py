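"""Tensor-based morphometry on a planted ~10% local expansion.

Warps a textured template by a known radial-expansion diffeomorphism for one
group, recovers deformation fields with multi-resolution demons registration,
and tests the log-Jacobian maps voxel-wise.  Takes about half a minute.
"""

import json

import hippomorph.experiments as ex

res = ex.tbm_expansion_experiment(seed=0)
print(json.dumps(res, indent=2))
print(
    f"\nthe planted peak expansion was {100 * res['planted_peak_expansion']:.0f}%; "
    f"{res['n_significant']} voxels are FDR-significant, overlapping the "
    f"half-maximum truth region (n={res['n_support']}) with "
    f"Dice {res['dice']:.2f}; every significant in-truth voxel has the "
    f"expansion sign ({100 * res['sign_agreement']:.0f}%)"
)
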