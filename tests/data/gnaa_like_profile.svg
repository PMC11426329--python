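<svg xmlns="http://www.w3.org/2000/svg" width="330.00" height="100.00" viewBox="0 0 330.00 100.00">
<line x1="40.00" y1="40.00" x2="270.00" y2="40.00" stroke="#2e7d32" stroke-width="4.50"><title>1-6 cis-W/W(G-C):234</title></line>
<line x1="86.00" y1="40.00" x2="224.00" y2="40.00" stroke="#2e7d32" stroke-width="4.32"><title>2-5 trans-H/S(G-A):223</title></line>
<circle cx="40.00" cy="40.00" r="11.00" fill="#54a24b" stroke="#222222" stroke-width="1.2"><title>col 1 G:234</title></circle>
<text x="40.00" y="42.50" font-size="7" text-anchor="middle" font-family="monospace">G</text>
<circle cx="86.00" cy="40.00" r="11.00" fill="#54a24b" stroke="#222222" stroke-width="1.2"><title>col 2 G:234</title></circle>
<text x="86.00" y="42.50" font-size="7" text-anchor="middle" font-family="monospace">G</text>
<circle cx="132.00" cy="40.00" r="11.00" fill="#e45756"><title>col 3 A:234</title></circle>
<text x="132.00" y="42.50" font-size="7" text-anchor="middle" font-family="monospace">A</text>
<circle cx="178.00" cy="40.00" r="11.00" fill="#e45756"><title>col 4 A:234</title></circle>
<text x="178.00" y="42.50" font-size="7" text-anchor="middle" font-family="monospace">A</text>
<circle cx="224.00" cy="40.00" r="11.00" fill="#e45756" stroke="#222222" stroke-width="1.2"><title>col 5 A:234</title></circle>
<text x="224.00" y="42.50" font-size="7" text-anchor="middle" font-family="monospace">A</text>
<circle cx="270.00" cy="40.00" r="11.00" fill="#4c78a8" stroke="#222222" stroke-width="1.2"><title>col 6 C:234</title></circle>
<text x="270.00" y="42.50" font-size="7" text-anchor="middle" font-family="monospace">C</text>
</svg>
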