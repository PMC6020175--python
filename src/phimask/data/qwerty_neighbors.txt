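# Physical neighbour sets on a QWERTY keyboard, one row per key:
# <key> <string of adjacent keys>. Used as the confusion prior of the
# keyboard-typo mutator (uniform over neighbours). Swap this file to use
# an empirically estimated confusion table instead.
1 2q
2 13qw
3 24we
4 35er
5 46rt
6 57ty
7 68yu
8 79ui
9 80io
0 9op
q 12wa
w 23qeas
e 34wrsd
r 45etdf
t 56ryfg
y 67tugh
u 78yihj
i 89uojk
o 90ipkl
p 0ol
a qwsz
s weadzx
d ersfxc
f rtdgcv
g tyfhvb
h yugjbn
j uihknm
k iojlm
l opkm
z asx
x zsdc
c xdfv
v cfgb
b vghn
n bhjm
m njk
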