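# synthetic BLOSUM-like raw substitution counts (not from real alignments)
# diagonally dominant by construction, so the row-sum-normalized
# odds-ratio matrix is positive definite
A C D E F G H I K L M N P Q R S T V W Y
80 6 3 5 1 3 5 4 4 6 3 1 6 5 4 4 2 6 2 1
6 82 3 4 2 2 2 2 5 3 1 4 6 2 4 6 5 5 5 3
3 3 72 6 3 1 5 2 3 6 5 2 1 5 3 3 4 2 4 5
5 4 6 82 2 3 5 4 6 1 4 3 4 3 1 2 1 2 3 1
1 2 3 2 98 5 2 2 6 4 5 4 1 6 3 6 5 4 6 3
3 2 1 3 5 57 1 1 1 1 3 2 2 2 4 4 1 2 5 6
5 2 5 5 2 1 99 4 5 3 3 1 5 5 4 5 4 6 1 3
4 2 2 4 2 1 4 72 5 1 3 3 2 3 1 6 1 3 1 5
4 5 3 6 6 1 5 5 95 5 3 6 3 3 5 1 5 4 4 5
6 3 6 1 4 1 3 1 5 92 3 5 6 3 6 5 3 4 1 2
3 1 5 4 5 3 3 3 3 3 74 1 1 6 6 3 6 2 2 1
1 4 2 3 4 2 1 3 6 5 1 73 1 3 5 4 2 6 2 3
6 6 1 4 1 2 5 2 3 6 1 1 72 1 6 4 1 5 4 6
5 2 5 3 6 2 5 3 3 3 6 3 1 95 5 1 6 3 3 5
4 4 3 1 3 4 4 1 5 6 6 5 6 5 99 4 3 6 1 5
4 6 3 2 6 4 5 6 1 5 3 4 4 1 4 95 1 3 4 2
2 5 4 1 5 1 4 1 5 3 6 2 1 6 3 1 78 2 4 6
6 5 2 2 4 2 6 3 4 4 2 6 5 3 6 3 2 89 6 1
2 5 4 3 6 5 1 1 4 1 2 2 4 3 1 4 4 6 71 3
1 3 5 1 3 6 3 5 5 2 1 3 6 5 5 2 6 1 3 90
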