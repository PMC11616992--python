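"""Side-chain distance distributions and hydrogen-bond occupancy.

A lysine side chain toggling between two carboxylate partners produces a
bimodal donor-acceptor distance distribution; a stable hydrogen bond
produces a single sharp peak.  The probability density function (PDF) and
the fraction of frames below a 3.5 Å heavy-atom cutoff quantify both.
"""

from lspnet import contact_occupancy, generate_distance_series, pdf_estimate

stable = generate_distance_series("unimodal", n=5000, seed=1, mu=2.8, sigma=0.12)
toggling = generate_distance_series("bimodal", n=5000, seed=2, mu1=2.8, mu2=6.0, w=0.5)

for name, series in [("stable H-bond", stable), ("toggling contact", toggling)]:
    curve = pdf_estimate(series)
    occ = contact_occupancy(series, cutoff=3.5)
    print(f"{name:17s}: mode at {curve.mode:4.2f} Å, occupancy(≤3.5 Å) = {occ:.2f}")

print()
print("Occupancy near 1 marks a maintained hydrogen bond; ~0.5 marks a side")
print("chain sharing its time between two partners, as in a toggling lysine.")
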