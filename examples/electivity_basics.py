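"""Manly's alpha and Chesson's electivity on a hand-sized example.

A bird's plots contain 50% habitat a, 30% b and 20% c, while the landscape
offers them at 20/30/50%.  Alpha rescales the use:availability ratios to
sum to 1; epsilon maps alpha onto [-1, 1] where 0 means use proportional to
availability.
"""

from habsel import alpha_from_epsilon, chesson_epsilon, manly_alpha

use = {"a": 0.5, "b": 0.3, "c": 0.2}
avail = {"a": 0.2, "b": 0.3, "c": 0.5}

alpha = manly_alpha(use, avail)
eps = chesson_epsilon(alpha)

print("use        :", use)
print("availability:", avail)
print("alpha      :", alpha.round(4).to_dict())
print("epsilon    :", eps.round(4).to_dict())
print("round trip :", alpha_from_epsilon(eps).round(4).to_dict())

# alpha sums to 1; habitat a is used 2.5x its availability, so alpha_a
# dominates (0.641) and eps_a > 0 marks preference, while c (used at 0.4x
# its availability) comes out avoided (eps_c < 0).
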