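"""Register-wise pairing free energy of an extended ASD across one TIR.

Plants the perfect 13-nt SD five nucleotides upstream of the start codon
and prints the energy profile as the ASD slides along the message.
"""

from sdscan import NNParameterTable, TIRWindow, scan_registers
from sdscan.genome_io import reverse_complement, transcribe

params = NNParameterTable.default()
tail = "GAUCACCUCCUUU"  # extended ASD, 16S nt 1532-1544 analogue
sd = transcribe(reverse_complement(tail))

upstream = "A" * 22 + sd.replace("U", "T") + "A" * 5  # SD ends 5 nt before AUG
tir = TIRWindow(gene="demo", seq=transcribe(upstream + "ATGGCAGCAGCA"))

print("register (nt between ASD 5' end and start codon) -> dG kcal/mol")
for score in scan_registers(tail, tir, range(0, 20), params):
    bar = "#" * int(-score.dG)
    print(f"{score.offset:3d}  {score.dG:7.2f}  {bar}")
# The minimum sits at register 6: the ASD 5' end (16S nt 1532) aligned six
# positions upstream of the start codon, i.e. the planted full 13-bp duplex.
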