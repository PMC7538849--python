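"""Compute the nine imaging biomarkers for a tiny hand-built tumor.

Builds a 9x9 single-slice tumor with a 3x3 central cavity, fills the mask,
and prints each biomarker with its meaning.
"""

import numpy as np

import lucency as lc

solid = np.ones((9, 9), dtype=bool)
solid[3:6, 3:6] = False  # a 3x3 air cavity in the middle

volume = lc.TumorVolume.from_arrays([solid])
vec = lc.compute_all(volume)

print("slice: 9x9 solid block, 3x3 central cavity")
print(f"  RDC      = {vec.rdc:.4f}   solid fraction of the mask (72/81)")
print(f"  RLC      = {vec.rlc:.4f}   lucent fraction (1 - RDC)")
print(f"  DoC      = {vec.doc:.4f}   |RDC - RLC|")
print(f"  AT_R     = {vec.at_r:.4f}   air-to-tissue ratio (9/72)")
print(f"  LoSA     = {vec.losa:.4f}   thickest wall: cavity rim to mask rim (px)")
print(f"  LoSA_R   = {vec.losa_r:.4f}   LoSA / Span")
print(f"  LoCA     = {vec.loca:.4f}   area-equivalent cavity diameter (px)")
print(f"  LoCA_R   = {vec.loca_r:.4f}   LoCA / Span")
print(f"  Solidity = {vec.solidity:.4f}   solid pixels over the bounding box")
print(f"  Span     = {lc.span(volume):.4f}   mask Feret diameter (px)")
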