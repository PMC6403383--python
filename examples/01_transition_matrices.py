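"""Estimate a Markov transition matrix from a DNA sequence.

Builds a short sequence, counts adjacent nucleotide pairs, estimates the
1-step transition matrix and raises it to step 3.
"""

from fisim import SequenceRecord, count_dinucleotides, \
    estimate_transition_matrix, k_step

record = SequenceRecord(id="demo", residues="ACGTACGTTGCAACGTGGCATT")

counts = count_dinucleotides(record)
print("dinucleotide counts (rows/cols in A, T, G, C order):")
print(counts.counts)

P = estimate_transition_matrix(counts)
print("\n1-step transition matrix (each row sums to 1):")
print(P.to_tsv())

P3 = k_step(P, 3)
print("3-step matrix (Chapman-Kolmogorov; rows mix toward stationarity):")
print(P3.to_tsv())
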