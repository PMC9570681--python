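"""Score compositions with the published index weights.

The published formula is
    index = ((0.7773*G + 0.5923*Y + 0.3753*R) - 37.53) / 40.20 * 100
so an all-green assortment scores 100, all-red scores 0, and all-yellow
scores about 54.
"""
from cfni import PUBLISHED_FORMULA, cfni_score

for g, y, r in [(100, 0, 0), (0, 100, 0), (0, 0, 100), (50.1, 26.0, 23.9), (60, 25, 15)]:
    score = cfni_score(
        PUBLISHED_FORMULA, {"pct_green": g, "pct_yellow": y, "pct_red": r}
    )
    print(f"G={g:5.1f}  Y={y:5.1f}  R={r:5.1f}  ->  index {score:6.2f}")
# Moving weight from red to yellow, or yellow to green, always raises the
# score; the typical pantry-cart mix near (50, 26, 24) lands in the mid 60s.
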