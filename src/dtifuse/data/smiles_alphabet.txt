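(
.
0
2
4
6
8
@
B
D
F
H
L
N
P
R
T
V
Z
\
b
d
f
h
l
n
r
t
#
%
)
+
-
/
1
3
5
7
9
=
A
C
E
G
I
K
M
O
S
U
W
Y
[
]
a
c
e
g
i
m
o
s
u
y
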