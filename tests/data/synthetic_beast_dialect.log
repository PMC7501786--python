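# Synthetic trace written by hand in the BEAST log dialect readable by Tracer.
# model: none (dialect-compatibility fixture only)
Sample	posterior	likelihood	prior	treeLikelihood	TreeHeight	popSize
0	-4637.8621	-4652.1003	14.2382	-4652.1003	0.8731	1.2051
1000	-4630.4418	-4645.9917	15.5499	-4645.9917	0.8012	0.9912
2000	-4628.0013	-4644.2207	16.2194	-4644.2207	0.7851	1.0873
3000	-4631.7754	-4646.8071	15.0317	-4646.8071	0.8144	1.1458
4000	-4629.3302	-4645.0166	15.6864	-4645.0166	0.7903	0.9734
5000	-4627.5487	-4643.9011	16.3524	-4643.9011	0.7798	1.0241
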